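"""End-to-end orchestration: QC -> selection -> collapsing -> relatedness ->
burden tests -> summaries, with on-disk stage outputs that support resuming.

Stage order and products:

1. ``load``        read VCF + annotation + panel + samples (+ PED/BED/deletions)
2. ``qc``          genotype filters then site filters (QC logs)
3. ``select``      candidate variant class sets
4. ``collapse``    recessive calls per variant set
5. ``relatedness`` PCA covariates, KING kinship, unrelated patient subset, ROH
6. ``burden``      Firth burden tests per variant set and gene subset
7. ``summary``     cohort summary statistics

``run_all(config, from_stage="burden")`` reuses the cached collapse and
relatedness TSVs in the output directory instead of recomputing them.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .collapse import calls_to_frame, collapse_recessive
from .filters import (
    apply_genotype_filters,
    apply_site_filters,
    select_candidate_variants,
)
from .io import load_cohort, write_report
from .model import Cohort, FilterConfig, RecessiveCall
from .popfreq import panel_cumulative_frequency, recessive_genotype_frequency
from .relatedness import (
    compute_pca,
    homozygosity_rate,
    king_kinship,
    unrelated_subset,
)
from .stats import burden_results_frame, burden_test, cohort_summary, summary_frame

STAGES = ("load", "qc", "select", "collapse", "relatedness", "burden", "summary")
VARIANT_SET_LABELS = ("primary", "plof", "plof_any_maf", "synonymous_control")


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage it occurred in."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = 10 + STAGES.index(stage)


@dataclass
class RunConfig:
    vcf: str
    annotation: str
    panel: str
    samples: str
    pedigree: Optional[str] = None
    mask: Optional[str] = None
    deletions: Optional[str] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    covariates: tuple[str, ...] = ("sex", "PC1", "PC2", "PC3", "PC4", "PC5")
    variant_sets: tuple[str, ...] = VARIANT_SET_LABELS
    seed: int = 0
    out_dir: str = "recburden_out"

    def validate(self) -> None:
        for name in ("vcf", "annotation", "panel", "samples"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise StageError("load", f"missing input file for {name}: {path}")
        for name in ("pedigree", "mask", "deletions"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise StageError("load", f"missing input file for {name}: {path}")


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as e:  # pragma: no cover - error-path plumbing
        raise StageError(stage, str(e)) from e


def _common_autosomal(cohort: Cohort, min_maf: float, min_call_rate: float) -> np.ndarray:
    v = cohort.variants
    maf = pd.to_numeric(v["maf"], errors="coerce").fillna(0.0).to_numpy()
    call_rate = 1.0 - v["site_missingness"].to_numpy()
    autosomal = ~cohort.is_x()
    return autosomal & (maf > min_maf) & (call_rate > min_call_rate)


def _calls_from_frame(df: pd.DataFrame) -> list[RecessiveCall]:
    return [
        RecessiveCall(
            sample_id=r.sample_id, gene=r.gene, mechanism=r.mechanism,
            variant_keys=tuple(str(r.variant_keys).split(";")),
            variant_set_label=r.variant_set_label,
        )
        for r in df.itertuples(index=False)
    ]


def run_all(config: RunConfig, from_stage: str = "load") -> dict:
    """Run the pipeline (optionally resuming from cached stage outputs).

    Returns a dict with the cohort summary, burden results, recessive
    calls, QC logs, kinship/ROH/PCA tables and the unrelated patient
    subset; all tables are also written under ``config.out_dir``.
    Deterministic: identical config produces byte-identical TSVs.
    """
    if from_stage not in ("load", "burden", "summary"):
        raise ValueError("from_stage must be one of load, burden, summary")
    out_dir = Path(config.out_dir)
    config.validate()
    fc = config.filter
    tables: dict[str, pd.DataFrame] = {}

    if from_stage == "load":
        cohort = _stage("load", load_cohort, config.vcf, config.annotation,
                        config.panel, config.samples, config.pedigree,
                        config.mask, config.deletions)

        gt_log = _stage("qc", apply_genotype_filters, cohort, fc)
        cohort, site_log = _stage("qc", apply_site_filters, cohort, fc)
        tables["qc_genotype_log"] = gt_log
        tables["qc_site_log"] = site_log
        if cohort.qc_anomalies is not None:
            tables["qc_anomalies"] = cohort.qc_anomalies

        panel_variants = cohort.variants[cohort.variants["gene"].notna()]
        sets = _stage("select", select_candidate_variants, panel_variants,
                      cohort.panel, fc)
        tables["variant_sets"] = pd.DataFrame(
            [
                {"variant_key": k, "variant_set_label": label}
                for label in VARIANT_SET_LABELS
                for k in sorted(sets.by_label(label))
            ]
        )

        calls: list[RecessiveCall] = []
        for label in config.variant_sets:
            # homozygous deletions are pLOF-class genotypes; they have no
            # place in the synonymous negative-control set
            dels = [] if label == "synonymous_control" else cohort.deletions
            calls.extend(
                _stage("collapse", collapse_recessive, cohort,
                       sets.by_label(label), label, deletions=dels)
            )
        tables["recessive_calls"] = calls_to_frame(calls)

        # relatedness: PCA + kinship on common well-called autosomal sites
        common = _stage("relatedness", _common_autosomal, cohort,
                        fc.pca_min_maf, fc.pca_min_call_rate)
        scores, explained = _stage("relatedness", compute_pca, cohort.gt[common])
        samples = cohort.samples.copy()
        for k in range(scores.shape[1]):
            samples[f"PC{k + 1}"] = scores[:, k]
        kin = _stage("relatedness", king_kinship, cohort.gt[common],
                     samples["sample_id"].tolist(), fc.kinship_threshold)
        tables["kinship_pairs"] = kin
        tables["pc_scores"] = samples[
            ["sample_id"] + [f"PC{k + 1}" for k in range(scores.shape[1])]
        ]

        roh_mask = (~cohort.is_x()) & (
            pd.to_numeric(cohort.variants["maf"], errors="coerce").fillna(0.0)
            > fc.roh_snp_min_maf
        ).to_numpy()
        roh = _stage(
            "relatedness", homozygosity_rate, cohort.gt[roh_mask],
            cohort.variants["chromosome"].to_numpy()[roh_mask],
            cohort.variants["position"].to_numpy()[roh_mask],
            samples["sample_id"].tolist(), fc,
        )
        samples["homozygosity_rate"] = roh.rates
        samples["is_consanguineous"] = roh.flags
        tables["roh_segments"] = roh.segments
        tables["roh_rates"] = samples[
            ["sample_id", "homozygosity_rate", "is_consanguineous"]
        ]

        case_ids = samples.loc[samples["group"] == "case", "sample_id"].tolist()
        primary_carriers = {
            c.sample_id for c in calls if c.variant_set_label == "primary"
        }
        unrelated_patients = _stage(
            "relatedness", unrelated_subset, case_ids, kin,
            fc.kinship_threshold, set(case_ids), primary_carriers,
        )
        tables["unrelated_patients"] = pd.DataFrame(
            {"sample_id": unrelated_patients}
        )
        tables["samples_augmented"] = samples
    else:
        # resume: reload cached stage outputs
        for name in ("recessive_calls", "samples_augmented", "kinship_pairs",
                     "unrelated_patients"):
            path = out_dir / f"{name}.tsv"
            if not path.exists():
                raise StageError("burden", f"cannot resume: missing {path}")
        calls_df = pd.read_csv(out_dir / "recessive_calls.tsv", sep="\t")
        calls = _calls_from_frame(calls_df)
        samples = pd.read_csv(out_dir / "samples_augmented.tsv", sep="\t",
                              float_precision="round_trip")
        tables["recessive_calls"] = calls_df
        tables["samples_augmented"] = samples
        tables["kinship_pairs"] = pd.read_csv(out_dir / "kinship_pairs.tsv", sep="\t",
                                              float_precision="round_trip")
        unrelated_patients = pd.read_csv(
            out_dir / "unrelated_patients.tsv", sep="\t"
        )["sample_id"].tolist()
        tables["unrelated_patients"] = pd.DataFrame({"sample_id": unrelated_patients})

    # --- burden ------------------------------------------------------------
    panel_df = pd.read_csv(config.panel, sep="\t", dtype=str)
    autosomal_genes = panel_df.loc[
        panel_df["chrom"].str.replace("chr", "") != "X", "gene"
    ].tolist()
    results = []
    for label in config.variant_sets:
        results.append(
            _stage("burden", burden_test, samples, calls, label, config.covariates)
        )
    results.append(
        _stage("burden", burden_test, samples, calls, "primary",
               config.covariates, autosomal_genes)
    )
    results.append(_stage("burden", burden_test, samples, calls, "primary", ()))
    tables["burden_results"] = burden_results_frame(results)

    # --- summary -----------------------------------------------------------
    summary = _stage("summary", cohort_summary, samples, calls, unrelated_patients)
    tables["summary"] = summary_frame(summary)

    # --- population genotype frequency from qualifying pLOF variants -------
    if from_stage == "load":
        tables["popfreq"] = _popfreq_table(cohort)

    write_report(
        tables, out_dir,
        metadata={
            "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
            "seed": config.seed,
            "version": __version__,
        },
    )
    return {
        "summary": summary,
        "burden": results,
        "calls": calls,
        "unrelated_patients": unrelated_patients,
        "samples": samples,
        "tables": tables,
    }


def _popfreq_table(cohort: Cohort) -> pd.DataFrame:
    """Hardy-Weinberg recessive genotype frequency per gene from the
    annotated population frequencies of rare pLOF panel variants."""
    v = cohort.variants
    plof = v[(v["gene"].notna()) & (v["consequence"] == "pLOF")]
    rows = []
    per_gene = []
    for gene, entry in sorted(cohort.panel.items()):
        qs = plof.loc[plof["gene"] == gene, "maf"].astype(float)
        qs = qs[(qs > 0) & (qs <= 0.5)].tolist()
        mode = "x_linked" if entry.is_x_linked else "autosomal"
        r = recessive_genotype_frequency(qs, mode, gene=gene)
        per_gene.append(r)
        rows.append({
            "gene": gene, "mode": mode, "cumulative_maf": r.cumulative_maf,
            "genotype_frequency": r.genotype_frequency,
        })
    agg_freq, agg_maf = panel_cumulative_frequency(per_gene)
    rows.append({"gene": "PANEL_TOTAL", "mode": "aggregate",
                 "cumulative_maf": agg_maf, "genotype_frequency": agg_freq})
    return pd.DataFrame(rows)
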