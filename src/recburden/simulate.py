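"""Synthetic case-control exome cohorts with the structure the pipeline assumes.

The generator emulates the statistical features the analysis relies on:
multi-population allele frequencies (Balding-Nichols divergence around
ancestral frequencies), Hardy-Weinberg genotypes within subpopulation,
excess homozygosity in consanguineous samples via planted autozygous
blocks, planted recessive carriers by mechanism, optional trios for
compound-het phasing, and optional genotype-level QC noise.  It writes the
same on-disk formats the loader consumes (VCF + annotation TSV + samples
TSV + PED + deletions TSV) plus a truth table of every planted carrier.

Non-planted rare panel variants are emitted heterozygous-only (and only in
females on X), a thinning approximation justified by their tiny
frequencies: recessive genotypes then arise exclusively from planting, so
carrier recovery can be scored exactly against the truth table.

``published_cohort_fixture`` builds the published pediatric pneumonia cohort: 112
patients (78 male / 34 female; 72 critical, 15 severe, 25 moderate) with
the 12 reported carriers, 1,224 asymptomatic/mildly infected controls
(306 male / 918 female) with 3 in-silico carriers of biochemically neutral
variants, 26 / 75 consanguineous samples, and four related patient pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import variant_key, write_vcf
from .model import GenePanelEntry

# hg19-scale autosome lengths (Mb); the map denominator for ROH rates
AUTOSOME_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51,
}
GENOME_BP = sum(AUTOSOME_MB.values()) * 1_000_000
_CHROM_ORDER = {c: i for i, c in enumerate(list(AUTOSOME_MB) + ["X"])}

#: the 15 candidate loci: 14 autosomal recessive genes plus X-linked TLR7.
#: MSC (gene-specific CADD cutoff) is configuration, not published data.
PANEL_15 = [
    ("TLR3", "4"), ("UNC93B1", "11"), ("TICAM1", "19"), ("TRAF3", "14"),
    ("TBK1", "12"), ("IRF3", "19"), ("IRF7", "11"), ("IRF9", "14"),
    ("IFNAR1", "21"), ("IFNAR2", "21"), ("STAT1", "2"), ("STAT2", "12"),
    ("TYK2", "19"), ("IFIH1", "2"), ("TLR7", "X"),
]


def default_panel(msc: float = 15.0) -> list[GenePanelEntry]:
    return [
        GenePanelEntry(g, c, msc, "XR" if c == "X" else "AR") for g, c in PANEL_15
    ]


@dataclass(frozen=True)
class QCNoise:
    """Per-genotype noise: depth, quality, allele balance, missingness."""

    dp_mean: float = 30.0
    gq_mean: float = 80.0
    gq_sd: float = 12.0
    missing_rate: float = 0.01


@dataclass(frozen=True)
class PlantSpec:
    gene: str
    mechanism: str  # homozygous | compound_het | hemizygous | homozygous_deletion
    group: str  # case | control
    count: int
    consequence: str = "missense"


@dataclass
class SimConfig:
    n_cases: int = 100
    n_controls: int = 300
    male_fraction_cases: float = 0.5
    male_fraction_controls: float = 0.5
    n_populations: int = 2
    fst: float = 0.05
    n_background_snps: int = 3000
    background_maf_range: tuple[float, float] = (0.2, 0.5)
    panel: list[GenePanelEntry] = field(default_factory=default_panel)
    panel_n_variants_per_gene: int = 4
    panel_maf_range: tuple[float, float] = (1e-6, 1e-2)
    planted: list[PlantSpec] = field(default_factory=list)
    consanguineous_fraction: float = 0.0
    inbreeding_coefficient: float = 0.0625
    autozygous_block_kb: float = 40_000.0
    n_trios: int = 0
    qc_noise: Optional[QCNoise] = None
    seed: int = 0
    related_pairs: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class SimulatedCohort:
    """Paths of the written cohort plus simulation internals for testing."""

    vcf: Path
    annotation: Path
    samples: Path
    panel: Path
    truth: Path
    pedigree: Optional[Path]
    deletions: Optional[Path]
    sample_table: pd.DataFrame
    truth_table: pd.DataFrame
    pop_of: np.ndarray
    subpop_freqs: np.ndarray  # background SNPs x populations
    background_chrom: np.ndarray
    background_pos: np.ndarray
    roh_truth: dict[str, list[tuple[str, int, int]]]


# ---------------------------------------------------------------------------
# building blocks


def balding_nichols(
    rng: np.random.Generator, p_ancestral: np.ndarray, k: int, fst: float
) -> np.ndarray:
    """Subpopulation frequencies around ancestral ones with divergence Fst.

    Each subpopulation draws p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F), so
    E[p_k] = p and Var[p_k] = F p (1 - p).
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must be in (0, 1)")
    a = p_ancestral * (1.0 - fst) / fst
    b = (1.0 - p_ancestral) * (1.0 - fst) / fst
    return rng.beta(a[:, None], b[:, None], size=(len(p_ancestral), k))


def _background_map(rng: np.random.Generator, n_snps: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct sorted autosomal SNV positions, density proportional to length."""
    chroms, positions = [], []
    total = sum(AUTOSOME_MB.values())
    remaining = n_snps
    items = list(AUTOSOME_MB.items())
    for i, (chrom, mb) in enumerate(items):
        n_c = remaining if i == len(items) - 1 else int(round(n_snps * mb / total))
        n_c = min(n_c, remaining)
        remaining -= n_c
        pos = np.unique(rng.integers(1, mb * 1_000_000, size=n_c * 2))
        pos = rng.choice(pos, size=min(n_c, len(pos)), replace=False)
        pos.sort()
        chroms.extend([chrom] * len(pos))
        positions.extend(pos.tolist())
    return np.array(chroms), np.array(positions, dtype=np.int64)


def simulate_autozygosity(
    hap1: np.ndarray,
    hap2: np.ndarray,
    chromosomes: np.ndarray,
    positions: np.ndarray,
    f_coefficient: float,
    block_length_kb: float = 40_000.0,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[str, int, int]]:
    """Force a fraction ``f_coefficient`` of the autosomal genome autozygous.

    Non-overlapping blocks of ``block_length_kb`` (the last truncated) are
    placed uniformly over the autosome-length map until exactly
    F x genome-length is covered; within each block the second haplotype is
    overwritten by the first.  Modifies ``hap2`` in place and returns the
    true block intervals (chromosome, start, end).
    """
    if f_coefficient >= 1.0 or f_coefficient < 0.0:
        raise ValueError("inbreeding coefficient must be in [0, 1)")
    if f_coefficient == 0.0:
        return []
    rng = rng or np.random.default_rng()
    target = f_coefficient * GENOME_BP
    block_bp = int(block_length_kb * 1000)
    chrom_names = list(AUTOSOME_MB)
    chrom_lens = np.array([AUTOSOME_MB[c] * 1_000_000 for c in chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {}
    intervals: list[tuple[str, int, int]] = []
    covered = 0
    while covered < target:
        length = min(block_bp, int(target - covered))
        for _ in range(1000):
            ci = rng.choice(len(chrom_names), p=probs)
            chrom = chrom_names[ci]
            limit = int(chrom_lens[ci]) - length
            if limit <= 1:
                continue
            start = int(rng.integers(1, limit))
            end = start + length
            if all(e <= start or s >= end for s, e in placed.get(chrom, [])):
                placed.setdefault(chrom, []).append((start, end))
                intervals.append((chrom, start, end))
                covered += length
                rows = (chromosomes == chrom) & (positions >= start) & (positions < end)
                hap2[rows] = hap1[rows]
                break
        else:
            raise RuntimeError("could not place autozygous block without overlap")
    return intervals


def _gene_layout(panel: Sequence[GenePanelEntry]) -> dict[str, tuple[str, int]]:
    """Deterministic (chromosome, base position) per panel gene."""
    return {
        g.gene_symbol: (g.chromosome, 10_000_000 + 2_000_000 * i)
        for i, g in enumerate(panel)
    }


_CLEAN_GT = np.array(
    ["./.:.:.:.,.", "0/0:30:99:30,0", "0/1:30:99:15,15", "1/1:30:99:0,30"],
    dtype=object,
)


def _gt_strings(
    dosage: np.ndarray,
    male: np.ndarray,
    is_x: bool,
    noise: Optional[QCNoise],
    rng: Optional[np.random.Generator],
) -> list[str]:
    """Per-sample FORMAT strings for one record.

    Internal dosage convention: males on X carry 0/1 (hemizygous); they are
    written diploid-coded (1 -> "1/1"), which the loader normalizes back.
    """
    w = dosage.astype(np.int64).copy()
    if is_x:
        w[male & (w == 1)] = 2
    if noise is None:
        return _CLEAN_GT[w + 1].tolist()
    n = len(w)
    dp = rng.poisson(noise.dp_mean, n)
    gq = np.clip(rng.normal(noise.gq_mean, noise.gq_sd, n), 1, 99).astype(int)
    miss = rng.random(n) < noise.missing_rate
    alt = np.where(w == 1, rng.binomial(np.maximum(dp, 0), 0.5), np.where(w >= 2, dp, 0))
    ref = dp - alt
    out = []
    gtmap = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for i in range(n):
        if miss[i] or w[i] < 0:
            out.append("./.:.:.:.,.")
        else:
            out.append(f"{gtmap[int(w[i])]}:{dp[i]}:{gq[i]}:{ref[i]},{alt[i]}")
    return out


@dataclass
class _Record:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str  # "." for background
    consequence: str
    maf: float
    cadd: float
    dosage: np.ndarray

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


def _write_cohort(
    out_dir: Path,
    sample_df: pd.DataFrame,
    records: list[_Record],
    truth: pd.DataFrame,
    ped: Optional[pd.DataFrame],
    deletions: Optional[pd.DataFrame],
    noise: Optional[QCNoise],
    rng: Optional[np.random.Generator],
) -> dict[str, Optional[Path]]:
    out_dir.mkdir(parents=True, exist_ok=True)
    male = (sample_df["sex"] == "male").to_numpy()
    records = sorted(records, key=lambda r: (_CHROM_ORDER[r.chrom], r.pos, r.ref, r.alt))

    def vcf_iter():
        for r in records:
            yield {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": [r.alt],
                "gt_strings": _gt_strings(r.dosage, male, r.chrom == "X", noise, rng),
            }

    paths: dict[str, Optional[Path]] = {}
    paths["vcf"] = out_dir / "cohort.vcf"
    contigs = sorted({r.chrom for r in records}, key=_CHROM_ORDER.get)
    write_vcf(paths["vcf"], sample_df["sample_id"], vcf_iter(), contigs=contigs)

    ann = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "gene": [r.gene for r in records],
            "consequence": [r.consequence for r in records],
            "gnomad_maf": [r.maf for r in records],
            "cadd": [r.cadd for r in records],
        }
    )
    paths["annotation"] = out_dir / "annotation.tsv"
    ann.to_csv(paths["annotation"], sep="\t", index=False, float_format="%.8g")

    paths["samples"] = out_dir / "samples.tsv"
    sample_df.to_csv(paths["samples"], sep="\t", index=False)

    paths["truth"] = out_dir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    if ped is not None and len(ped):
        paths["pedigree"] = out_dir / "cohort.ped"
        ped.to_csv(paths["pedigree"], sep="\t", index=False, header=False)
    else:
        paths["pedigree"] = None

    if deletions is not None and len(deletions):
        paths["deletions"] = out_dir / "deletions.tsv"
        deletions.to_csv(paths["deletions"], sep="\t", index=False)
    else:
        paths["deletions"] = None
    return paths


def write_panel(panel: Sequence[GenePanelEntry], path: Path) -> Path:
    pd.DataFrame(
        {
            "gene": [g.gene_symbol for g in panel],
            "chrom": [g.chromosome for g in panel],
            "msc": [g.msc for g in panel],
            "inheritance": [g.inheritance for g in panel],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# general generator


def generate_cohort(config: SimConfig, out_dir: str | os.PathLike) -> SimulatedCohort:
    """Generate and write a full synthetic cohort; returns paths + truth.

    Identical config (including seed) produces byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    panel_by_gene = {g.gene_symbol: g for g in config.panel}

    # --- samples ------------------------------------------------------------
    ids, sexes, groups, severities = [], [], [], []
    n_male_cases = int(round(config.male_fraction_cases * config.n_cases))
    for i in range(config.n_cases):
        ids.append(f"CASE{i + 1:04d}")
        sexes.append("male" if i < n_male_cases else "female")
        groups.append("case")
        severities.append(["moderate", "severe", "critical"][int(rng.integers(3))])
    n_male_ctrl = int(round(config.male_fraction_controls * config.n_controls))
    for i in range(config.n_controls):
        ids.append(f"CTRL{i + 1:04d}")
        sexes.append("male" if i < n_male_ctrl else "female")
        groups.append("control")
        severities.append("asymptomatic" if rng.random() < 0.7 else "mild")
    pop_of = rng.integers(0, config.n_populations, size=len(ids))
    for a, b, _g in config.related_pairs:
        pop_of[ids.index(b)] = pop_of[ids.index(a)]

    sample_df = pd.DataFrame(
        {"sample_id": ids, "sex": sexes, "group": groups,
         "severity": severities, "family_id": [""] * len(ids)}
    )

    # --- planted carriers ---------------------------------------------------
    male_arr = np.array(sexes) == "male"
    group_arr = np.array(groups)
    plant_assignments: list[dict] = []  # sample idx, gene, mechanism, consequence
    used_per_gene: dict[str, set[int]] = {}
    for spec in config.planted:
        gene = spec.gene
        if gene not in panel_by_gene:
            raise ValueError(f"planted gene {gene} not in panel")
        entry = panel_by_gene[gene]
        if spec.mechanism == "hemizygous" and not entry.is_x_linked:
            raise ValueError(f"hemizygous plant requested on autosome ({gene})")
        pool = np.flatnonzero(
            (group_arr == spec.group)
            & (male_arr if spec.mechanism == "hemizygous" else True)
        )
        used = used_per_gene.setdefault(gene, set())
        pool = np.array([i for i in pool if i not in used])
        if spec.count > len(pool):
            raise ValueError(
                f"planted carrier count {spec.count} exceeds available "
                f"{spec.group} samples for {gene}"
            )
        chosen = rng.choice(pool, size=spec.count, replace=False)
        for c in chosen:
            used.add(int(c))
            plant_assignments.append(
                {"idx": int(c), "gene": gene, "mechanism": spec.mechanism,
                 "consequence": spec.consequence}
            )

    # --- trios for compound-het phasing ------------------------------------
    ped_rows = []
    trio_children = [
        a for a in plant_assignments if a["mechanism"] == "compound_het"
    ][: config.n_trios]
    parent_ids: list[tuple[str, str, str]] = []  # child, father, mother
    for a in trio_children:
        child = ids[a["idx"]]
        fa, mo = f"FA_{child}", f"MO_{child}"
        parent_ids.append((child, fa, mo))
        for pid, sex in ((fa, "male"), (mo, "female")):
            sample_df.loc[len(sample_df)] = [pid, sex, "control", "asymptomatic", child]
        sample_df.loc[sample_df["sample_id"] == child, "family_id"] = child
        ped_rows.append([child, child, fa, mo,
                         1 if male_arr[a["idx"]] else 2, 2])
        ped_rows.append([child, fa, "0", "0", 1, 1])
        ped_rows.append([child, mo, "0", "0", 2, 1])
    n_total = len(sample_df)
    pop_full = np.concatenate(
        [pop_of] + [np.repeat(pop_of[ids.index(c)], 2) for c, _f, _m in parent_ids]
    ) if parent_ids else pop_of
    all_ids = sample_df["sample_id"].tolist()
    idx_of = {s: i for i, s in enumerate(all_ids)}
    male_full = (sample_df["sex"] == "male").to_numpy()

    # --- background genotypes ----------------------------------------------
    bg_chrom, bg_pos = _background_map(rng, config.n_background_snps)
    v = len(bg_pos)
    lo, hi = config.background_maf_range
    p_anc = rng.uniform(lo, hi, size=v)
    freqs = balding_nichols(rng, p_anc, config.n_populations, config.fst)
    h1 = np.empty((v, n_total), dtype=bool)
    h2 = np.empty((v, n_total), dtype=bool)
    for k in range(config.n_populations):
        cols = np.flatnonzero(pop_full == k)
        if len(cols) == 0:
            continue
        pk = freqs[:, k][:, None]
        h1[:, cols] = rng.random((v, len(cols))) < pk
        h2[:, cols] = rng.random((v, len(cols))) < pk

    # children of trios re-derive their haplotypes from the parents
    for child, fa, mo in parent_ids:
        ci, fi, mi = idx_of[child], idx_of[fa], idx_of[mo]
        pick_f = rng.random(v) < 0.5
        pick_m = rng.random(v) < 0.5
        h1[:, ci] = np.where(pick_f, h1[:, fi], h2[:, fi])
        h2[:, ci] = np.where(pick_m, h1[:, mi], h2[:, mi])

    for a, b, gamma in config.related_pairs:
        ai, bi = idx_of[a], idx_of[b]
        pick = rng.random(v) < 0.5
        donor = np.where(pick, h1[:, ai], h2[:, ai])
        take = rng.random(v) < gamma
        h1[take, bi] = donor[take]

    # --- consanguinity ------------------------------------------------------
    roh_truth: dict[str, list[tuple[str, int, int]]] = {}
    if config.consanguineous_fraction > 0:
        n_cons = int(round(config.consanguineous_fraction * (len(ids))))
        chosen = rng.choice(len(ids), size=n_cons, replace=False)
        for c in chosen:
            roh_truth[ids[c]] = simulate_autozygosity(
                h1[:, c], h2[:, c], bg_chrom, bg_pos,
                config.inbreeding_coefficient, config.autozygous_block_kb, rng,
            )

    bg_dosage = h1.astype(np.int8) + h2.astype(np.int8)

    records = [
        _Record(bg_chrom[i], int(bg_pos[i]), "A", "G", ".", "other",
                float(p_anc[i]), 1.0, bg_dosage[i])
        for i in range(v)
    ]

    # --- panel variants ------------------------------------------------------
    layout = _gene_layout(config.panel)
    truth_rows = []
    deletion_rows = []
    next_offset: dict[str, int] = {}

    def new_site(gene: str, consequence: str, maf: float, cadd: float) -> _Record:
        chrom, base = layout[gene]
        off = next_offset.get(gene, 0)
        next_offset[gene] = off + 1
        rec = _Record(chrom, base + 100 * off, "C", "T", gene, consequence,
                      maf, cadd, np.zeros(n_total, dtype=np.int8))
        records.append(rec)
        return rec

    plant_sites: dict[tuple[str, str], list[_Record]] = {}
    for a in plant_assignments:
        gene, mech = a["gene"], a["mechanism"]
        entry = panel_by_gene[gene]
        if mech == "homozygous_deletion":
            sid = all_ids[a["idx"]]
            chrom, base = layout[gene]
            deletion_rows.append(
                {"sample_id": sid, "gene": gene, "chrom": chrom,
                 "start": base, "end": base + 5000, "copy_number": 0}
            )
            truth_rows.append({"sample_id": sid, "gene": gene,
                               "mechanism": "homozygous_deletion",
                               "variant_keys": f"del:{chrom}:{base}-{base + 5000}",
                               "group": group_arr[a["idx"]] if a["idx"] < len(ids) else "control",
                               "deleterious": True})
            continue
        skey = (gene, mech)
        if skey not in plant_sites:
            cadd = entry.msc + 10.0
            maf = 1e-5
            n_sites = 2 if mech == "compound_het" else 1
            plant_sites[skey] = [
                new_site(gene, a["consequence"], maf, cadd) for _ in range(n_sites)
            ]
        sites = plant_sites[skey]
        sid = all_ids[a["idx"]]
        if mech == "homozygous":
            sites[0].dosage[a["idx"]] = 2
            mech_label = "homozygous"
            keys = [sites[0].key]
        elif mech == "hemizygous":
            sites[0].dosage[a["idx"]] = 1
            mech_label = "hemizygous"
            keys = [sites[0].key]
        elif mech == "compound_het":
            sites[0].dosage[a["idx"]] = 1
            sites[1].dosage[a["idx"]] = 1
            in_trio = any(c == sid for c, _f, _m in parent_ids)
            if in_trio:
                fa, mo = next((f, m) for c, f, m in parent_ids if c == sid)
                sites[0].dosage[idx_of[fa]] = 1
                sites[1].dosage[idx_of[mo]] = 1
                mech_label = "compound_het_confirmed"
            else:
                mech_label = "compound_het_potential"
            keys = [s.key for s in sites]
        else:
            raise ValueError(f"unknown plant mechanism {mech}")
        truth_rows.append({"sample_id": sid, "gene": gene, "mechanism": mech_label,
                           "variant_keys": ";".join(keys),
                           "group": group_arr[a["idx"]] if a["idx"] < len(ids) else "control",
                           "deleterious": True})

    # background (non-planted) panel variation: heterozygous-only
    csq_classes = ["missense", "pLOF", "synonymous", "essential_splice", "other"]
    csq_probs = [0.5, 0.1, 0.25, 0.05, 0.1]
    cadd_mean = {"missense": 18.0, "pLOF": 35.0, "synonymous": 3.0,
                 "essential_splice": 30.0, "other": 5.0}
    lo_q, hi_q = config.panel_maf_range
    for g in config.panel:
        gene = g.gene_symbol
        used = used_per_gene.setdefault(gene, set())
        for _ in range(config.panel_n_variants_per_gene):
            csq = csq_classes[int(rng.choice(len(csq_classes), p=csq_probs))]
            q = float(np.exp(rng.uniform(np.log(lo_q), np.log(hi_q))))
            cadd = float(max(0.1, rng.normal(cadd_mean[csq], 4.0)))
            rec = new_site(gene, csq, q, cadd)
            eligible = (
                np.flatnonzero(~male_full) if g.is_x_linked else np.arange(n_total)
            )
            qualifying = (
                csq in ("missense", "pLOF", "essential_splice")
                and cadd > g.msc
            )
            if qualifying:
                eligible = np.array([i for i in eligible if i not in used])
            k = int(rng.binomial(len(eligible), min(1.0, 2 * q))) if len(eligible) else 0
            if k > 0:
                chosen = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
                rec.dosage[chosen] = 1
                if qualifying:
                    used.update(int(c) for c in chosen)

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "mechanism", "variant_keys", "group", "deleterious"],
    ).sort_values(["gene", "sample_id"]).reset_index(drop=True)
    ped = pd.DataFrame(ped_rows) if ped_rows else None
    deletions = pd.DataFrame(deletion_rows) if deletion_rows else None

    paths = _write_cohort(out_dir, sample_df, records, truth, ped, deletions,
                          config.qc_noise, rng)
    panel_path = write_panel(config.panel, out_dir / "panel.tsv")
    return SimulatedCohort(
        vcf=paths["vcf"], annotation=paths["annotation"], samples=paths["samples"],
        panel=panel_path,
        truth=paths["truth"], pedigree=paths["pedigree"], deletions=paths["deletions"],
        sample_table=sample_df, truth_table=truth, pop_of=pop_full,
        subpop_freqs=freqs, background_chrom=bg_chrom, background_pos=bg_pos,
        roh_truth=roh_truth,
    )


# ---------------------------------------------------------------------------
# the published pediatric cohort fixture


#: carriers among the 112 patients: (id, gene, mechanism, sex, severity)
FIXTURE_PATIENT_CARRIERS = [
    ("P001", "STAT2", "compound_het_potential", "male", "critical"),
    ("P002", "TYK2", "homozygous", "female", "moderate"),
    ("P003", "TYK2", "homozygous", "male", "critical"),
    ("P004", "TYK2", "homozygous", "male", "critical"),
    ("P005", "TLR7", "hemizygous", "male", "severe"),
    ("P006", "TLR7", "hemizygous", "male", "severe"),
    ("P007", "TLR7", "hemizygous", "male", "severe"),
    ("P008", "TLR7", "hemizygous", "male", "critical"),
    ("P009", "TLR7", "hemizygous", "male", "moderate"),
    ("P010", "TLR7", "hemizygous", "male", "critical"),
    ("P011", "TLR7", "hemizygous", "male", "critical"),
    ("P012", "IFNAR1", "homozygous_deletion", "female", "critical"),
]

#: in-silico qualifying but biochemically neutral carriers among controls
FIXTURE_CONTROL_CARRIERS = [
    ("K0001", "TLR7", "hemizygous", "male"),
    ("K0307", "IFIH1", "homozygous", "female"),
    ("K0002", "IRF7", "homozygous", "male"),
]

#: the four related patient pairs (two carrier pairs, two non-carrier
#: critical pairs); gamma=0.5 plants second-degree sharing (phi ~ 0.125)
FIXTURE_RELATED_PAIRS = [
    ("P006", "P007", 0.5),
    ("P008", "P009", 0.5),
    ("P013", "P014", 0.5),
    ("P015", "P016", 0.5),
]


def _fixture_samples() -> pd.DataFrame:
    """112 patients (78 M / 34 F; 72 critical, 15 severe, 25 moderate) and
    1,224 controls (306 M / 918 F), carriers and related pairs encoded."""
    rows = []
    carrier_info = {c[0]: c for c in FIXTURE_PATIENT_CARRIERS}
    for i in range(1, 113):
        sid = f"P{i:03d}"
        if sid in carrier_info:
            _, _, _, sex, severity = carrier_info[sid]
        else:
            # non-carriers: 65 critical (P013-P077), 12 severe (P078-P089),
            # 23 moderate (P090-P112); males P013-P080 (68, for 78 total)
            severity = "critical" if i <= 77 else ("severe" if i <= 89 else "moderate")
            sex = "male" if i <= 80 else "female"
        rows.append({"sample_id": sid, "sex": sex, "group": "case",
                     "severity": severity, "family_id": ""})
    for i in range(1, 1225):
        sid = f"K{i:04d}"
        rows.append({"sample_id": sid, "sex": "male" if i <= 306 else "female",
                     "group": "control",
                     "severity": "asymptomatic" if i % 2 else "mild",
                     "family_id": ""})
    return pd.DataFrame(rows)


def _fixture_pops(sample_df: pd.DataFrame) -> np.ndarray:
    """Three ancestry groups; patients Middle-East-weighted, controls
    Europe-weighted, related pair members share a population."""
    pops = np.zeros(len(sample_df), dtype=np.int64)
    for i, sid in enumerate(sample_df["sample_id"]):
        if sid.startswith("P"):
            j = int(sid[1:])
            pops[i] = 0 if j % 10 < 6 else (1 if j % 10 < 8 else 2)
        else:
            j = int(sid[1:])
            pops[i] = 0 if j % 8 == 0 else (2 if j % 8 == 7 else 1)
    idx_of = {s: i for i, s in enumerate(sample_df["sample_id"])}
    for a, b, _g in FIXTURE_RELATED_PAIRS:
        pops[idx_of[b]] = pops[idx_of[a]]
    return pops


#: patients flagged consanguineous (26): the four autosomal-genotype
#: carriers, one removed member of a non-carrier related pair, and 21
#: further critical non-carriers
FIXTURE_CONSANGUINEOUS_PATIENTS = (
    ["P002", "P003", "P004", "P012", "P014"]
    + [f"P{i:03d}" for i in range(17, 38)]
)
#: controls flagged consanguineous (75): the homozygous-variant control
#: carrier plus 74 others
FIXTURE_CONSANGUINEOUS_CONTROLS = ["K0307"] + [f"K{i:04d}" for i in range(400, 474)]


def published_cohort_fixture(
    out_dir: str | os.PathLike,
    seed: int = 0,
    n_background_snps: int = 24_000,
    fst: float = 0.05,
    inbreeding_coefficient: float = 0.04,
    msc: float = 15.0,
) -> SimulatedCohort:
    """Write the published-cohort fixture as an on-disk cohort.

    Encodes the published cohort facts: 112 patients / 1,224 controls with
    their sex and severity margins, the 12 patient carriers (compound-het
    STAT2; homozygous TYK2 x3; hemizygous TLR7 x7; IFNAR1 homozygous
    deletion), the 3 control carriers of neutral in-silico-qualifying
    variants, 26 / 75 consanguineous samples (planted autozygous blocks
    yielding >1% genome in runs of homozygosity), and four related patient
    pairs (the two TLR7 carrier pairs and two non-carrier critical pairs).
    Background SNVs carry the population structure used by PCA, kinship
    and ROH estimation.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    panel = default_panel(msc)
    sample_df = _fixture_samples()
    pops = _fixture_pops(sample_df)
    ids = sample_df["sample_id"].tolist()
    idx_of = {s: i for i, s in enumerate(ids)}
    n = len(ids)

    bg_chrom, bg_pos = _background_map(rng, n_background_snps)
    v = len(bg_pos)
    p_anc = rng.uniform(0.2, 0.5, size=v)
    freqs = balding_nichols(rng, p_anc, 3, fst)
    h1 = np.empty((v, n), dtype=bool)
    h2 = np.empty((v, n), dtype=bool)
    for k in range(3):
        cols = np.flatnonzero(pops == k)
        pk = freqs[:, k][:, None]
        h1[:, cols] = rng.random((v, len(cols))) < pk
        h2[:, cols] = rng.random((v, len(cols))) < pk

    for a, b, gamma in FIXTURE_RELATED_PAIRS:
        ai, bi = idx_of[a], idx_of[b]
        pick = rng.random(v) < 0.5
        donor = np.where(pick, h1[:, ai], h2[:, ai])
        take = rng.random(v) < gamma
        h1[take, bi] = donor[take]

    roh_truth: dict[str, list[tuple[str, int, int]]] = {}
    for sid in FIXTURE_CONSANGUINEOUS_PATIENTS + FIXTURE_CONSANGUINEOUS_CONTROLS:
        c = idx_of[sid]
        roh_truth[sid] = simulate_autozygosity(
            h1[:, c], h2[:, c], bg_chrom, bg_pos,
            inbreeding_coefficient, 40_000.0, rng,
        )

    bg_dosage = h1.astype(np.int8) + h2.astype(np.int8)
    records = [
        _Record(bg_chrom[i], int(bg_pos[i]), "A", "G", ".", "other",
                float(p_anc[i]), 1.0, bg_dosage[i])
        for i in range(v)
    ]

    layout = _gene_layout(panel)

    def site(gene: str, offset: int, csq: str, maf: float, cadd: float,
             dosages: dict[str, int]) -> _Record:
        chrom, base = layout[gene]
        rec = _Record(chrom, base + 100 * offset, "C", "T", gene, csq,
                      maf, cadd, np.zeros(n, dtype=np.int8))
        for sid, d in dosages.items():
            rec.dosage[idx_of[sid]] = d
        records.append(rec)
        return rec

    truth_rows = []

    def record_truth(sid, gene, mech, keys, deleterious):
        truth_rows.append({
            "sample_id": sid, "gene": gene, "mechanism": mech,
            "variant_keys": ";".join(keys),
            "group": "case" if sid.startswith("P") else "control",
            "deleterious": deleterious,
        })

    # P1: STAT2 compound heterozygote (S613F-like missense + Q685X-like stop)
    s_a = site("STAT2", 0, "missense", 1e-5, 25.0, {"P001": 1})
    s_b = site("STAT2", 1, "pLOF", 0.0, 38.0, {"P001": 1})
    record_truth("P001", "STAT2", "compound_het_potential", [s_a.key, s_b.key], True)
    # P2-P4: shared homozygous TYK2 frameshift
    t = site("TYK2", 0, "pLOF", 2e-5, 35.0, {"P002": 2, "P003": 2, "P004": 2})
    for sid in ("P002", "P003", "P004"):
        record_truth(sid, "TYK2", "homozygous", [t.key], True)
    # P5-P11: hemizygous TLR7 missense variants (shared within related pairs)
    tlr7_sites = {
        "I174R": site("TLR7", 0, "missense", 0.0, 28.0, {"P005": 1}),
        "N75H": site("TLR7", 1, "missense", 1e-5, 27.0, {"P006": 1, "P007": 1}),
        "D244Y": site("TLR7", 2, "missense", 1e-5, 26.0, {"P008": 1, "P009": 1}),
        "H781L": site("TLR7", 3, "missense", 0.0, 25.0, {"P010": 1}),
        "L372M": site("TLR7", 4, "missense", 1e-5, 24.0, {"P011": 1}),
    }
    for sid, var in (("P005", "I174R"), ("P006", "N75H"), ("P007", "N75H"),
                     ("P008", "D244Y"), ("P009", "D244Y"), ("P010", "H781L"),
                     ("P011", "L372M")):
        record_truth(sid, "TLR7", "hemizygous", [tlr7_sites[var].key], True)
    # P12: IFNAR1 homozygous deletion (consumed from the deletions table)
    del_row = {"sample_id": "P012", "gene": "IFNAR1", "chrom": "21",
               "start": 34_719_302, "end": 34_723_696, "copy_number": 0}
    record_truth("P012", "IFNAR1", "homozygous_deletion",
                 ["del:21:34719302-34723696"], True)
    # control carriers: qualify in silico, biochemically neutral
    c1 = site("TLR7", 5, "missense", 1e-5, 22.0, {"K0001": 1})
    record_truth("K0001", "TLR7", "hemizygous", [c1.key], False)
    c2 = site("IFIH1", 0, "missense", 5e-5, 20.0, {"K0307": 2})
    record_truth("K0307", "IFIH1", "homozygous", [c2.key], False)
    c3 = site("IRF7", 0, "missense", 8e-5, 18.0, {"K0002": 2})
    record_truth("K0002", "IRF7", "homozygous", [c3.key], False)

    # benign panel variation exercising the selector: rare synonymous
    # homozygotes (negative-control set), a common missense, a low-CADD
    # missense, and a common pLOF (pLOF-any-MAF set only)
    site("STAT1", 0, "synonymous", 5e-5, 2.0,
         {"P050": 2, "K0500": 2, "K0501": 2, "K0502": 1})
    site("TLR3", 0, "missense", 1e-2, 10.0,
         {f"K{i:04d}": 1 for i in range(100, 130)})
    site("UNC93B1", 0, "missense", 2e-5, 8.0, {"P060": 1, "K0600": 1})
    site("IFNAR2", 0, "pLOF", 5e-3, 38.0, {"K0700": 1, "K0701": 1})

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "mechanism", "variant_keys", "group", "deleterious"],
    )
    deletions = pd.DataFrame([del_row])
    paths = _write_cohort(out_dir, sample_df, records, truth, None, deletions,
                          None, None)
    panel_path = write_panel(panel, out_dir / "panel.tsv")
    return SimulatedCohort(
        vcf=paths["vcf"], annotation=paths["annotation"], samples=paths["samples"],
        panel=panel_path, truth=paths["truth"], pedigree=None,
        deletions=paths["deletions"], sample_table=sample_df, truth_table=truth,
        pop_of=pops, subpop_freqs=freqs, background_chrom=bg_chrom,
        background_pos=bg_pos, roh_truth=roh_truth,
    )


# ---------------------------------------------------------------------------
# lightweight null cohorts for burden-test calibration


def simulate_null_cohort(
    rng: np.random.Generator,
    n_samples: int = 400,
    n_snps: int = 300,
    fst: float = 0.1,
    case_prob: tuple[float, float] = (0.5, 0.2),
    carrier_prob: tuple[float, float] = (0.10, 0.03),
) -> tuple[pd.DataFrame, np.ndarray]:
    """One ancestry-confounded null cohort for type-I-error calibration.

    Two subpopulations; both case status and carrier status depend on the
    subpopulation but are independent of each other given it, so the
    covariate-adjusted burden test should be calibrated while the
    unadjusted one is confounded.  Returns (samples with sex, group and
    genotype-PCA covariate columns PC1..PC5, carrier indicator).
    """
    from .relatedness import compute_pca

    pop = rng.integers(0, 2, size=n_samples)
    case = rng.random(n_samples) < np.array(case_prob)[pop]
    carrier = rng.random(n_samples) < np.array(carrier_prob)[pop]
    p_anc = rng.uniform(0.2, 0.5, size=n_snps)
    freqs = balding_nichols(rng, p_anc, 2, fst)
    gt = rng.binomial(2, freqs[:, pop]).astype(np.int8)
    scores, _ = compute_pca(gt)
    samples = pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n_samples)],
        "sex": np.where(rng.random(n_samples) < 0.5, "male", "female"),
        "group": np.where(case, "case", "control"),
        "severity": np.where(case, "severe", "asymptomatic"),
    })
    for k in range(scores.shape[1]):
        samples[f"PC{k + 1}"] = scores[:, k]
    return samples, carrier
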