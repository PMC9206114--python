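"""Domain types shared across the pipeline.

The pipeline studies enrichment in rare recessive genotypes (homozygous,
compound-heterozygous, hemizygous, or homozygous-deletion) at a small panel
of candidate genes, in a case-control exome cohort.  Genotypes are held in
dense numpy matrices (variants x samples) inside :class:`Cohort`; the
dataclasses below are the per-record views used at module boundaries and in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

#: consequence classes understood by the candidate-variant selector
CONSEQUENCES = ("pLOF", "missense", "essential_splice", "synonymous", "other")

#: recessive mechanisms, strongest first (used to pick one call per gene)
MECHANISMS = (
    "homozygous_deletion",
    "homozygous",
    "hemizygous",
    "compound_het_confirmed",
    "compound_het_potential",
)

SEVERITIES = ("asymptomatic", "mild", "moderate", "severe", "critical")
#: severities that define a case (pneumonia requiring hospitalization)
CASE_SEVERITIES = ("moderate", "severe", "critical")


@dataclass(frozen=True)
class GenePanelEntry:
    """One candidate gene with its inheritance mode and CADD cutoff (MSC)."""

    gene_symbol: str
    chromosome: str
    msc: float
    inheritance: str  # "AR" | "XR"

    @property
    def is_x_linked(self) -> bool:
        return self.chromosome == "X"

    def __post_init__(self) -> None:
        if self.msc <= 0:
            raise ValueError(f"{self.gene_symbol}: msc must be > 0")
        if self.inheritance not in ("AR", "XR"):
            raise ValueError(f"{self.gene_symbol}: inheritance must be AR or XR")
        if self.is_x_linked != (self.inheritance == "XR"):
            raise ValueError(
                f"{self.gene_symbol}: inheritance {self.inheritance} inconsistent "
                f"with chromosome {self.chromosome}"
            )


@dataclass(frozen=True)
class VariantSite:
    """One biallelic annotated variant (VCF convention: 1-based position)."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str]
    consequence: str
    maf: float
    cadd: float
    n_alt_alleles_at_locus: int = 1
    site_missingness: float = 0.0
    span_nt: int = 1
    in_masked_region: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf {self.maf} outside [0,1] at {self.key}")
        if self.position < 1:
            raise ValueError(f"position {self.position} < 1")
        if self.span_nt < 1:
            raise ValueError(f"span_nt {self.span_nt} < 1")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}:{self.alt_allele}"


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample per-site call with the QC fields the genotype filters use."""

    sample_id: str
    variant_key: str
    dosage: int  # 0/1/2; males on X: 0/1 (hemizygous)
    depth: int
    genotype_quality: int
    allele_depths: tuple[int, int]
    is_missing: bool = False


@dataclass
class SampleRecord:
    sample_id: str
    sex: str  # "male" | "female"
    group: str  # "case" | "control"
    severity: str
    family_id: Optional[str] = None
    ancestry_pcs: Optional[np.ndarray] = None
    homozygosity_rate: Optional[float] = None

    @property
    def is_consanguineous(self) -> Optional[bool]:
        if self.homozygosity_rate is None:
            return None
        return self.homozygosity_rate > 0.01


@dataclass(frozen=True)
class FilterConfig:
    """QC and analysis thresholds.

    Defaults are the published study settings: genotypes are dropped below
    8x depth or GQ 20, heterozygous calls with a minor-read ratio under 20%,
    sites with >4 alternate alleles, >10% missingness, spanning >15 nt, or
    inside the low-complexity/decoy mask; candidate variants must have
    population MAF < 1e-4 and CADD above the gene's MSC.
    """

    min_depth: int = 8
    min_gq: int = 20
    min_minor_read_ratio: float = 0.20
    max_alt_alleles: int = 4
    max_site_missingness: float = 0.10
    max_span_nt: int = 15
    candidate_max_maf: float = 1e-4
    pca_min_maf: float = 0.01
    pca_min_call_rate: float = 0.99
    kinship_threshold: float = 0.0442
    roh_window_kb: float = 1000.0
    roh_window_snps: int = 50
    roh_window_max_het: int = 1
    roh_window_max_missing: int = 5
    roh_hit_fraction: float = 0.05
    roh_min_segment_snps: int = 100
    roh_min_segment_kb: float = 1000.0
    roh_snp_min_maf: float = 0.05
    consanguinity_threshold: float = 0.01
    #: strict CADD > MSC per the stated rule; set False for >=
    cadd_strictly_greater: bool = True
    #: the ">4 alleles" rule counts ALT alleles at the locus
    count_alt_alleles_only: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if v <= 0:
                raise ValueError(f"FilterConfig.{f.name} must be strictly positive")


@dataclass(frozen=True)
class DeletionCall:
    """Pre-computed homozygous (copy number 0) deletion overlapping a gene."""

    sample_id: str
    gene: str
    chromosome: str
    start: int
    end: int
    copy_number: int = 0

    def __post_init__(self) -> None:
        if self.copy_number != 0:
            raise ValueError("only homozygous deletions (copy_number 0) are modeled")
        if self.start > self.end:
            raise ValueError("deletion start > end")


@dataclass(frozen=True)
class RecessiveCall:
    """Collapsed per-sample per-gene recessive genotype."""

    sample_id: str
    gene: str
    mechanism: str
    variant_keys: tuple[str, ...]
    variant_set_label: str

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism}")
        if self.mechanism.startswith("compound_het") and len(self.variant_keys) < 2:
            raise ValueError("compound het requires >=2 variant keys")


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float
    degree: str


def kinship_degree(phi: float) -> str:
    """Relationship degree from the kinship coefficient (KING thresholds)."""
    if phi > 0.354:
        return "duplicate_MZ"
    if phi > 0.177:
        return "first"
    if phi > 0.0884:
        return "second"
    if phi >= 0.0442:
        return "third"
    return "unrelated"


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    start: int
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ROH segment end must exceed start")


@dataclass
class FirthFit:
    beta: np.ndarray
    hat_diagonals: np.ndarray
    penalized_loglik: float
    converged: bool
    n_iterations: int
    fisher_information: np.ndarray | None = None


@dataclass
class BurdenResult:
    variant_set_label: str
    carriers_cases: int
    n_cases: int
    carriers_controls: int
    n_controls: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates_used: tuple[str, ...] = ()
    gene_subset: Optional[tuple[str, ...]] = None
    warning: Optional[str] = None


@dataclass(frozen=True)
class PopFreqResult:
    gene: str
    cumulative_maf: float
    genotype_frequency: float
    mode: str  # "autosomal" | "x_linked"
    male_fraction: float = 0.5


class Cohort:
    """In-memory cohort: variant table, genotype matrices, sample table.

    ``variants`` is a DataFrame indexed 0..V-1 with columns chromosome,
    position, ref, alt, key, gene, consequence, maf, cadd,
    n_alt_alleles_at_locus, span_nt, in_masked_region, site_missingness.
    ``gt`` is int8 (V x N): dosage 0/1/2, males on X 0/1, -1 missing.
    ``dp``/``gq`` int32 (-1 = field absent), ``ad_ref``/``ad_alt`` int32
    (-1 = absent).  ``samples`` holds sample_id, sex, group, severity,
    family_id and is extended in place by downstream stages (PCs,
    homozygosity_rate, is_consanguineous).
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        gt: np.ndarray,
        dp: np.ndarray,
        gq: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
        samples: pd.DataFrame,
        panel: dict[str, GenePanelEntry],
        pedigree: Optional[pd.DataFrame] = None,
        deletions: Optional[list[DeletionCall]] = None,
        qc_anomalies: Optional[pd.DataFrame] = None,
    ) -> None:
        if gt.shape != (len(variants), len(samples)):
            raise ValueError("genotype matrix shape mismatch")
        self.variants = variants
        self.gt = gt
        self.dp = dp
        self.gq = gq
        self.ad_ref = ad_ref
        self.ad_alt = ad_alt
        self.samples = samples
        self.panel = panel
        self.pedigree = pedigree
        self.deletions = deletions or []
        self.qc_anomalies = qc_anomalies

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def male_mask(self) -> np.ndarray:
        return (self.samples["sex"] == "male").to_numpy()

    @property
    def case_mask(self) -> np.ndarray:
        return (self.samples["group"] == "case").to_numpy()

    def is_x(self) -> np.ndarray:
        """Boolean per-variant mask for chromosome X sites."""
        chrom = self.variants["chromosome"].astype(str)
        return chrom.str.replace("chr", "", regex=False).eq("X").to_numpy()

    def recompute_missingness(self) -> None:
        self.variants["site_missingness"] = (self.gt < 0).mean(axis=1)
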