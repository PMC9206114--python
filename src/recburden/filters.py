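"""Genotype-level QC, site-level QC, and candidate-variant selection.

Genotype rule: a call is set missing when depth < 8, genotype quality < 20,
or (heterozygous calls only) the minor-read ratio
min(ref_reads, alt_reads) / (ref_reads + alt_reads) is below 0.20.
Homozygous and hemizygous calls are exempt from the ratio rule, which would
otherwise reject essentially every good homozygote.

Site rule: a variant is dropped when it falls in the low-complexity/decoy
mask, has more than four alternate alleles at its locus, exceeds 10%
missing genotypes (recomputed after the genotype filter), or spans more
than 15 nucleotides.

Candidate selection: nonsynonymous (missense + pLOF) and essential-splice
variants with population MAF < 1e-4 and CADD above the gene-specific
mutation significance cutoff; plus a pLOF-only subset, a pLOF set without
any MAF restriction, and a rare-synonymous negative-control set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Cohort, FilterConfig

NONSYNONYMOUS = ("missense", "pLOF", "essential_splice")


@dataclass(frozen=True)
class VariantClassSets:
    primary_set: frozenset[str]
    plof_set: frozenset[str]
    plof_any_maf_set: frozenset[str]
    synonymous_control_set: frozenset[str]

    def by_label(self, label: str) -> frozenset[str]:
        return {
            "primary": self.primary_set,
            "plof": self.plof_set,
            "plof_any_maf": self.plof_any_maf_set,
            "synonymous_control": self.synonymous_control_set,
        }[label]


def apply_genotype_filters(cohort: Cohort, config: FilterConfig | None = None) -> pd.DataFrame:
    """Set failing genotypes missing in place; return the QC log.

    The log has one row per (variant, sample, reason); a call failing two
    rules appears twice so per-reason counts are complete.  Idempotent.
    """
    config = config or FilterConfig()
    gt, dp, gq = cohort.gt, cohort.dp, cohort.gq
    adr, ada = cohort.ad_ref, cohort.ad_alt
    called = gt >= 0

    hemi = cohort.is_x()[:, None] & cohort.male_mask[None, :]
    het = (gt == 1) & ~hemi

    fail_dp = called & (dp >= 0) & (dp < config.min_depth)
    fail_gq = called & (gq >= 0) & (gq < config.min_gq)

    ad_known = (adr >= 0) & (ada >= 0) & ((adr + ada) > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = (adr + ada).astype(np.float64)
        mrr = np.minimum(adr, ada) / np.where(total > 0, total, np.nan)
    fail_ratio = het & ad_known & (mrr < config.min_minor_read_ratio)
    fail_ad_absent = het & ~ad_known

    log_rows = []
    keys = cohort.variants["key"].to_numpy()
    sample_ids = cohort.samples["sample_id"].to_numpy()
    for reason, mask in (
        ("low_depth", fail_dp),
        ("low_gq", fail_gq),
        ("low_minor_read_ratio", fail_ratio),
        ("ad_absent_het", fail_ad_absent),
    ):
        vi, si = np.nonzero(mask)
        for v, s in zip(vi, si):
            log_rows.append({"variant_key": keys[v], "sample_id": sample_ids[s],
                             "reason": reason})

    cohort.gt = np.where(fail_dp | fail_gq | fail_ratio | fail_ad_absent, -1, gt).astype(np.int8)
    cohort.recompute_missingness()
    return pd.DataFrame(log_rows, columns=["variant_key", "sample_id", "reason"])


def apply_site_filters(
    cohort: Cohort, config: FilterConfig | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Drop failing sites; return (filtered cohort, exclusion log)."""
    config = config or FilterConfig()
    cohort.recompute_missingness()
    v = cohort.variants
    reasons = {
        "masked_region": v["in_masked_region"].to_numpy(dtype=bool),
        "multiallelic_gt4": v["n_alt_alleles_at_locus"].to_numpy() > config.max_alt_alleles,
        "high_missingness": v["site_missingness"].to_numpy() > config.max_site_missingness,
        "span_gt15nt": v["span_nt"].to_numpy() > config.max_span_nt,
    }
    drop = np.zeros(len(v), dtype=bool)
    rows = []
    for reason, mask in reasons.items():
        drop |= mask
        for i in np.flatnonzero(mask):
            rows.append({"variant_key": v["key"].iloc[i], "reason": reason})
    keep = ~drop
    filtered = Cohort(
        variants=v.loc[keep].reset_index(drop=True),
        gt=cohort.gt[keep],
        dp=cohort.dp[keep],
        gq=cohort.gq[keep],
        ad_ref=cohort.ad_ref[keep],
        ad_alt=cohort.ad_alt[keep],
        samples=cohort.samples,
        panel=cohort.panel,
        pedigree=cohort.pedigree,
        deletions=cohort.deletions,
        qc_anomalies=cohort.qc_anomalies,
    )
    return filtered, pd.DataFrame(rows, columns=["variant_key", "reason"])


def select_candidate_variants(
    variants: pd.DataFrame,
    panel: dict,
    config: FilterConfig | None = None,
) -> VariantClassSets:
    """Build the four analysis variant sets from annotated panel variants.

    ``variants`` must carry key, gene, consequence, maf, cadd and contain
    panel genes only.
    """
    config = config or FilterConfig()
    unknown = set(variants["gene"].dropna()) - set(panel)
    if unknown or variants["gene"].isna().any():
        bad = sorted(unknown) + (["<missing>"] if variants["gene"].isna().any() else [])
        raise ValueError(f"variants in unknown gene(s): {bad}")

    msc = variants["gene"].map(lambda g: panel[g].msc).to_numpy(dtype=float)
    cadd = variants["cadd"].to_numpy(dtype=float)
    maf = variants["maf"].to_numpy(dtype=float)
    csq = variants["consequence"].to_numpy()
    keys = variants["key"].to_numpy()

    passes_msc = cadd > msc if config.cadd_strictly_greater else cadd >= msc
    rare = maf < config.candidate_max_maf
    nonsyn = np.isin(csq, NONSYNONYMOUS)
    is_plof = csq == "pLOF"

    primary = nonsyn & rare & passes_msc
    plof = primary & is_plof
    syn = (csq == "synonymous") & rare

    return VariantClassSets(
        primary_set=frozenset(keys[primary]),
        plof_set=frozenset(keys[plof]),
        plof_any_maf_set=frozenset(keys[is_plof]),
        synonymous_control_set=frozenset(keys[syn]),
    )
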