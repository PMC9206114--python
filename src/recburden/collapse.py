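"""Collapse qualifying variants into per-sample per-gene recessive calls.

A sample is a carrier at a gene when it has a homozygous qualifying
variant, is a male hemizygote for a qualifying variant of an X-linked
gene, carries two or more distinct qualifying heterozygous variants of
the same gene (compound heterozygosity: trans-confirmed when trio
genotypes establish one variant per parent, potential otherwise, and
dropped when trio genotypes prove the cis configuration), or carries a
pre-computed homozygous deletion of the gene.  One call is emitted per
sample-gene pair, with the strongest mechanism.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import Cohort, DeletionCall, MECHANISMS, RecessiveCall

_RANK = {m: i for i, m in enumerate(MECHANISMS)}


def _trio_phase(
    child_sites: list[int],
    gt: np.ndarray,
    child_col: int,
    father_col: Optional[int],
    mother_col: Optional[int],
) -> str:
    """Classify >=2 het qualifying sites as confirmed / potential / cis.

    ``confirmed``: some pair of sites has determined opposite parental
    origins (trans).  ``cis``: every site has a determined origin and all
    share one parent.  Anything else (parent missing or ambiguous
    genotypes) stays ``potential``.
    """
    if father_col is None or mother_col is None:
        return "potential"
    origins = []
    for v in child_sites:
        f = gt[v, father_col]
        m = gt[v, mother_col]
        if f < 0 or m < 0:
            origins.append("unknown")
        elif f > 0 and m == 0:
            origins.append("paternal")
        elif m > 0 and f == 0:
            origins.append("maternal")
        else:
            origins.append("ambiguous")
    if "paternal" in origins and "maternal" in origins:
        return "confirmed"
    determined = [o for o in origins if o in ("paternal", "maternal")]
    if len(determined) == len(origins) and len(set(determined)) == 1:
        return "cis"
    return "potential"


def collapse_recessive(
    cohort: Cohort,
    variant_set: Iterable[str],
    variant_set_label: str,
    pedigree: Optional[pd.DataFrame] = None,
    deletions: Optional[list[DeletionCall]] = None,
) -> list[RecessiveCall]:
    """Emit recessive genotype calls for every sample x panel gene.

    ``variant_set`` is a set of qualifying variant keys (from the
    candidate selector) restricted to panel genes; ``deletions`` are
    homozygous deletion calls joined by gene symbol.  The genotype matrix
    must be post-QC.
    """
    keys = set(variant_set)
    pedigree = pedigree if pedigree is not None else cohort.pedigree
    deletions = deletions if deletions is not None else cohort.deletions

    sample_ids = cohort.samples["sample_id"].tolist()
    col_of = {s: i for i, s in enumerate(sample_ids)}
    male = cohort.male_mask

    father_of: dict[int, Optional[int]] = {}
    mother_of: dict[int, Optional[int]] = {}
    if pedigree is not None and len(pedigree):
        for row in pedigree.itertuples(index=False):
            for parent in (row.father_id, row.mother_id):
                if parent not in (None, "0", "") and not pd.isna(parent):
                    if parent not in col_of:
                        raise ValueError(
                            f"pedigree references unknown sample {parent}"
                        )
            if row.sample_id in col_of:
                c = col_of[row.sample_id]
                father_of[c] = col_of.get(row.father_id)
                mother_of[c] = col_of.get(row.mother_id)

    v = cohort.variants
    in_set = v["key"].isin(keys).to_numpy()
    vv = v.loc[in_set]
    best: dict[tuple[str, str], RecessiveCall] = {}

    def offer(call: RecessiveCall) -> None:
        k = (call.sample_id, call.gene)
        cur = best.get(k)
        if cur is None or _RANK[call.mechanism] < _RANK[cur.mechanism]:
            best[k] = call

    for gene, gdf in vv.groupby("gene", sort=True):
        entry = cohort.panel.get(gene)
        x_linked = entry.is_x_linked if entry is not None else False
        idx = gdf.index.to_numpy()
        order = np.argsort(gdf["position"].to_numpy(), kind="stable")
        idx = idx[order]
        sub = cohort.gt[idx]  # k x N
        gkeys = v["key"].to_numpy()[idx]

        hom_rows, hom_cols = np.nonzero(sub == 2)
        for r, c in zip(hom_rows, hom_cols):
            offer(RecessiveCall(sample_ids[c], gene, "homozygous",
                                (gkeys[r],), variant_set_label))
        if x_linked:
            hemi = (sub == 1) & male[None, :]
            for r, c in zip(*np.nonzero(hemi)):
                offer(RecessiveCall(sample_ids[c], gene, "hemizygous",
                                    (gkeys[r],), variant_set_label))
            het = (sub == 1) & ~male[None, :]
        else:
            het = sub == 1
        n_het = het.sum(axis=0)
        for c in np.flatnonzero(n_het >= 2):
            sites = [int(i) for i in np.flatnonzero(het[:, c])]
            phase = _trio_phase(
                [int(idx[i]) for i in sites], cohort.gt, c,
                father_of.get(c), mother_of.get(c),
            )
            if phase == "cis":
                continue
            mech = ("compound_het_confirmed" if phase == "confirmed"
                    else "compound_het_potential")
            offer(RecessiveCall(sample_ids[c], gene, mech,
                                tuple(gkeys[i] for i in sites), variant_set_label))

    for d in deletions or []:
        if d.gene not in cohort.panel:
            continue
        if d.sample_id not in col_of:
            raise ValueError(f"deletion call for unknown sample {d.sample_id}")
        offer(RecessiveCall(
            d.sample_id, d.gene, "homozygous_deletion",
            (f"del:{d.chromosome}:{d.start}-{d.end}",), variant_set_label,
        ))

    return sorted(best.values(), key=lambda c: (c.gene, c.sample_id))


def carriers(calls: Iterable[RecessiveCall]) -> set[str]:
    """Panel-level carrier status: samples with at least one call."""
    return {c.sample_id for c in calls}


def calls_to_frame(calls: Iterable[RecessiveCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "gene": c.gene,
                "mechanism": c.mechanism,
                "variant_keys": ";".join(c.variant_keys),
                "variant_set_label": c.variant_set_label,
            }
            for c in calls
        ],
        columns=["sample_id", "gene", "mechanism", "variant_keys", "variant_set_label"],
    )


def check_segregation(
    pedigree: pd.DataFrame,
    cohort: Cohort,
    gene: str,
    calls: list[RecessiveCall],
) -> dict[str, dict]:
    """Per-family consistency of proband calls with recessive inheritance.

    Mendelian checks: each genotyped parent of an autosomal homozygote must
    carry at least one allele; the mother of a hemizygote must carry the
    allele.  Unaffected relatives who share the full recessive genotype are
    reported as incomplete-penetrance observations, not inconsistencies.
    PED phenotype "2" marks affected.
    """
    sample_ids = cohort.samples["sample_id"].tolist()
    col_of = {s: i for i, s in enumerate(sample_ids)}
    for row in pedigree.itertuples(index=False):
        for s in (row.sample_id, row.father_id, row.mother_id):
            if s not in (None, "0", "") and not pd.isna(s) and s not in col_of:
                raise ValueError(f"pedigree references unknown sample {s}")

    key_row = {k: i for i, k in enumerate(cohort.variants["key"])}
    ped = pedigree.set_index("sample_id")
    affected = set(ped.index[ped["phenotype"].astype(str) == "2"])
    gene_calls = {c.sample_id: c for c in calls if c.gene == gene}

    reports: dict[str, dict] = {}
    for fam, members in pedigree.groupby("family_id"):
        inconsistencies: list[str] = []
        gpos_unaffected: list[str] = []
        fam_ids = members["sample_id"].tolist()
        for sid in fam_ids:
            call = gene_calls.get(sid)
            if call is None:
                continue
            row = ped.loc[sid]
            fa, mo = row["father_id"], row["mother_id"]
            if call.mechanism == "homozygous":
                vk = call.variant_keys[0]
                vi = key_row.get(vk)
                for parent, label in ((fa, "father"), (mo, "mother")):
                    if parent in col_of and vi is not None:
                        if cohort.gt[vi, col_of[parent]] == 0:
                            inconsistencies.append(
                                f"{sid}: {label} {parent} carries zero "
                                f"alleles of {vk}"
                            )
            elif call.mechanism == "hemizygous":
                vk = call.variant_keys[0]
                vi = key_row.get(vk)
                if mo in col_of and vi is not None:
                    if cohort.gt[vi, col_of[mo]] == 0:
                        inconsistencies.append(
                            f"{sid}: mother {mo} does not carry {vk}"
                        )
        # relatives sharing the full genotype but unaffected
        for sid in fam_ids:
            if sid in gene_calls and sid not in affected:
                gpos_unaffected.append(sid)
        reports[str(fam)] = {
            "consistent": not inconsistencies,
            "inconsistencies": inconsistencies,
            "genotype_positive_unaffected": sorted(gpos_unaffected),
        }
    return reports
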