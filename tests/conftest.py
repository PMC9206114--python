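"""Shared fixtures: in-memory cohorts, a toy on-disk cohort, and one
session-scoped run of the full pipeline on the published-cohort fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recburden.io import write_vcf
from recburden.model import Cohort, GenePanelEntry
from recburden.pipeline import RunConfig, run_all
from recburden.simulate import published_cohort_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_cohort(
    variants: list[dict],
    gt: np.ndarray,
    samples: list[dict],
    panel: dict[str, GenePanelEntry] | None = None,
    dp: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    ad_ref: np.ndarray | None = None,
    ad_alt: np.ndarray | None = None,
    **kwargs,
) -> Cohort:
    """Build an in-memory cohort with clean default QC fields."""
    vdf = pd.DataFrame(variants)
    for col, default in (
        ("gene", None), ("consequence", "other"), ("maf", 0.0), ("cadd", 1.0),
        ("n_alt_alleles_at_locus", 1), ("span_nt", 1),
        ("in_masked_region", False), ("site_missingness", 0.0),
    ):
        if col not in vdf.columns:
            vdf[col] = default
    if "key" not in vdf.columns:
        vdf["key"] = [
            f"{r.chromosome}:{r.position}:{r.ref}:{r.alt}"
            for r in vdf.itertuples(index=False)
        ]
    gt = np.asarray(gt, dtype=np.int8)
    shape = gt.shape

    def full(arr, fill):
        return (np.full(shape, fill, dtype=np.int32) if arr is None
                else np.asarray(arr, dtype=np.int32))

    ad_r = np.where(gt == 1, 15, np.where(gt == 2, 0, 30)).astype(np.int32)
    ad_a = np.where(gt == 1, 15, np.where(gt == 2, 30, 0)).astype(np.int32)
    cohort = Cohort(
        variants=vdf,
        gt=gt,
        dp=full(dp, 30),
        gq=full(gq, 99),
        ad_ref=ad_r if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=ad_a if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
        samples=pd.DataFrame(samples),
        panel=panel or {},
        **kwargs,
    )
    cohort.recompute_missingness()
    return cohort


def sample_row(sid, sex="female", group="control", severity="asymptomatic"):
    return {"sample_id": sid, "sex": sex, "group": group,
            "severity": severity, "family_id": ""}


def variant_row(chrom, pos, ref="A", alt="G", **kw):
    row = {"chromosome": chrom, "position": pos, "ref": ref, "alt": alt}
    row.update(kw)
    return row


@pytest.fixture
def toy_cohort_files(tmp_path):
    """Toy on-disk cohort: 3 sites x 2 samples, one chrX site, BED mask."""
    samples = ["S1", "S2"]  # S1 male, S2 female
    records = [
        {"chrom": "1", "pos": 100, "ref": "A", "alt": ["G"],
         "gt_strings": ["0/1:30:99:15,15", "0/0:30:99:30,0"]},
        {"chrom": "1", "pos": 200, "ref": "C", "alt": ["T"],
         "gt_strings": ["1/1:30:99:0,30", "0/1:30:99:15,15"]},
        {"chrom": "X", "pos": 500, "ref": "G", "alt": ["A"],
         "gt_strings": ["1/1:30:99:0,30", "0/1:30:99:15,15"]},
    ]
    vcf = tmp_path / "toy.vcf"
    write_vcf(vcf, samples, records, contigs=["1", "X"])
    ann = tmp_path / "ann.tsv"
    pd.DataFrame({
        "chrom": ["1", "1", "X"], "pos": [100, 200, 500],
        "ref": ["A", "C", "G"], "alt": ["G", "T", "A"],
        "gene": ["GENE1", "GENE1", "XGENE"],
        "consequence": ["missense", "synonymous", "missense"],
        "gnomad_maf": [1e-5, 1e-5, 1e-5], "cadd": [25.0, 2.0, 25.0],
    }).to_csv(ann, sep="\t", index=False)
    panel = tmp_path / "panel.tsv"
    pd.DataFrame({
        "gene": ["GENE1", "XGENE"], "chrom": ["1", "X"],
        "msc": [15.0, 15.0], "inheritance": ["AR", "XR"],
    }).to_csv(panel, sep="\t", index=False)
    smp = tmp_path / "samples.tsv"
    pd.DataFrame({
        "sample_id": samples, "sex": ["male", "female"],
        "group": ["case", "control"], "severity": ["critical", "asymptomatic"],
        "family_id": ["", ""],
    }).to_csv(smp, sep="\t", index=False)
    bed = tmp_path / "mask.bed"
    bed.write_text("1\t150\t250\n")  # masks 1:151-250, i.e. the pos-200 site
    return {"vcf": vcf, "annotation": ann, "panel": panel,
            "samples": smp, "mask": bed, "dir": tmp_path}


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The published-cohort fixture pushed through the full pipeline once."""
    base = tmp_path_factory.mktemp("pubcohort")
    sim = published_cohort_fixture(base / "fixture", seed=1)
    config = RunConfig(
        vcf=str(sim.vcf), annotation=str(sim.annotation), panel=str(sim.panel),
        samples=str(sim.samples), deletions=str(sim.deletions),
        seed=1, out_dir=str(base / "out"),
    )
    out = run_all(config)
    out["sim"] = sim
    out["config"] = config
    return out
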