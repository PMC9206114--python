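"""Readers and writers for the external formats the pipeline touches.

Formats: multi-sample VCF 4.2 (GT/DP/GQ/AD), annotation TSV
(chrom, pos, ref, alt, gene, consequence, gnomad_maf, cadd), panel TSV
(gene, chrom, msc, inheritance), samples TSV (sample_id, sex, group,
severity, family_id), 6-column PED, BED (0-based half-open) mask, and a
deletions TSV (sample_id, gene, chrom, start, end, copy_number).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import Cohort, DeletionCall, GenePanelEntry

_INT_MISSING = -1


class CohortLoadError(ValueError):
    """Raised when the on-disk cohort violates a loader contract."""


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then prefix so indels get a canonical key.

    Full left-alignment against the reference sequence is not attempted
    (no FASTA is consumed); suffix/prefix trimming gives a canonical
    representation for the parsimony-normalized records the pipeline emits
    and consumes.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_panel(path: str | os.PathLike) -> dict[str, GenePanelEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    panel: dict[str, GenePanelEntry] = {}
    for row in df.itertuples(index=False):
        if row.gene in panel:
            raise CohortLoadError(f"duplicate panel gene {row.gene}")
        panel[row.gene] = GenePanelEntry(
            gene_symbol=row.gene,
            chromosome=str(row.chrom).replace("chr", ""),
            msc=float(row.msc),
            inheritance=row.inheritance,
        )
    return panel


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "sex", "group", "severity"}
    missing = required - set(df.columns)
    if missing:
        raise CohortLoadError(f"samples table missing columns: {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise CohortLoadError(f"duplicated sample IDs: {sorted(dup.unique())}")
    if "family_id" not in df.columns:
        df["family_id"] = pd.NA
    return df.reset_index(drop=True)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": int, "ref": str, "alt": str, "gene": str,
               "consequence": str, "gnomad_maf": float, "cadd": float},
    )
    keys = []
    for row in df.itertuples(index=False):
        pos, ref, alt = normalize_variant(row.pos, row.ref, row.alt)
        keys.append(variant_key(str(row.chrom).replace("chr", ""), pos, ref, alt))
    df = df.assign(key=keys)
    dup = df["key"][df["key"].duplicated()]
    if len(dup):
        raise CohortLoadError(f"duplicate annotation keys: {sorted(dup.unique())[:10]}")
    return df.set_index("key")


def read_bed_mask(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Per-chromosome (n,2) arrays of 0-based half-open intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom.replace("chr", ""), []).append((int(start), int(end)))
    return {c: np.array(sorted(iv), dtype=np.int64) for c, iv in out.items()}


def position_in_mask(mask: dict[str, np.ndarray], chrom: str, pos: int) -> bool:
    """Is 1-based position ``pos`` inside a BED interval [s, e) (i.e. s+1..e)?"""
    iv = mask.get(chrom.replace("chr", ""))
    if iv is None or not len(iv):
        return False
    return bool(np.any((iv[:, 0] < pos) & (pos <= iv[:, 1])))


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["family_id", "sample_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str, comment="#",
    )
    return df


def read_deletions(path: str | os.PathLike) -> list[DeletionCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str, "chrom": str})
    return [
        DeletionCall(
            sample_id=r.sample_id, gene=r.gene,
            chromosome=str(r.chrom).replace("chr", ""),
            start=int(r.start), end=int(r.end), copy_number=int(r.copy_number),
        )
        for r in df.itertuples(index=False)
    ]


def _record_dosage_split(variant, n_alts: int) -> list[np.ndarray]:
    """Per-alt dosage vectors for a multi-allelic record (slow path)."""
    per_alt = [np.zeros(len(variant.genotypes), dtype=np.int8) for _ in range(n_alts)]
    for i, g in enumerate(variant.genotypes):
        alleles = [a for a in g[:-1]]  # last element is phased flag
        if any(a < 0 for a in alleles):
            for d in per_alt:
                d[i] = _INT_MISSING
            continue
        for ai in range(1, n_alts + 1):
            per_alt[ai - 1][i] = sum(1 for a in alleles if a == ai)
    return per_alt


def _format_field(variant, name: str, n: int, col: int = 0) -> np.ndarray:
    arr = variant.format(name)
    if arr is None:
        return np.full(n, _INT_MISSING, dtype=np.int32)
    vals = arr[:, col].astype(np.int64, copy=False)
    vals = np.where((vals < 0) | (vals > 2**30), _INT_MISSING, vals)
    return vals.astype(np.int32)


def load_cohort(
    vcf_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    panel_path: str | os.PathLike,
    samples_path: str | os.PathLike,
    pedigree_path: Optional[str | os.PathLike] = None,
    mask_path: Optional[str | os.PathLike] = None,
    deletions_path: Optional[str | os.PathLike] = None,
) -> Cohort:
    """Read the full cohort and join the VCF to its annotation.

    Male chrX genotypes are normalized to hemizygous dosage {0,1};
    biologically inconsistent male X heterozygotes are set missing and
    logged in ``cohort.qc_anomalies``.  Multi-allelic rows are split into
    biallelic records (the pre-split ALT count is retained for the
    multi-allelic site filter).
    """
    samples = read_samples(samples_path)
    panel = read_panel(panel_path)
    annotation = read_annotation(annotation_path)
    mask = read_bed_mask(mask_path) if mask_path else {}
    pedigree = read_pedigree(pedigree_path) if pedigree_path else None
    deletions = read_deletions(deletions_path) if deletions_path else None

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    if len(set(vcf_samples)) != len(vcf_samples):
        raise CohortLoadError("duplicated sample ID in VCF header")
    if set(vcf_samples) != set(samples["sample_id"]):
        only_vcf = sorted(set(vcf_samples) - set(samples["sample_id"]))[:5]
        only_meta = sorted(set(samples["sample_id"]) - set(vcf_samples))[:5]
        raise CohortLoadError(
            f"VCF / metadata sample mismatch (vcf-only {only_vcf}, meta-only {only_meta})"
        )
    # order samples as in the VCF so matrix columns line up
    samples = samples.set_index("sample_id").loc[vcf_samples].reset_index()
    n = len(vcf_samples)
    male = (samples["sex"] == "male").to_numpy()
    female = ~male

    rows: list[dict] = []
    gt_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    adr_rows: list[np.ndarray] = []
    ada_rows: list[np.ndarray] = []
    anomalies: list[dict] = []

    for variant in vcf:
        chrom = variant.CHROM.replace("chr", "")
        is_x = chrom == "X"
        n_alts = len(variant.ALT)
        dp = _format_field(variant, "DP", n)
        gq = _format_field(variant, "GQ", n)
        ad = variant.format("AD")

        if is_x:
            # haploid coding is only legal for males
            ploidy = np.array([len(g) - 1 for g in variant.genotypes])
            bad = female & (ploidy == 1)
            if bad.any():
                ids = [vcf_samples[i] for i in np.flatnonzero(bad)[:5]]
                raise CohortLoadError(
                    f"female sample(s) with hemizygous encoding at "
                    f"{chrom}:{variant.POS}: {ids}"
                )

        if n_alts == 1:
            dos = variant.gt_types.astype(np.int8)  # gts012: 0,1,2 dosage; 3 unknown
            dos = np.where(dos == 3, _INT_MISSING, dos).astype(np.int8)
            per_alt = [dos]
        else:
            per_alt = _record_dosage_split(variant, n_alts)

        for ai, dos in enumerate(per_alt):
            dos = dos.copy()
            if is_x:
                het_male = male & (dos == 1)
                # a male cannot be heterozygous on (non-PAR) X: set missing
                for i in np.flatnonzero(het_male):
                    anomalies.append(
                        {"sample_id": vcf_samples[i],
                         "variant": f"{chrom}:{variant.POS}",
                         "reason": "male_x_heterozygous"}
                    )
                dos[het_male] = _INT_MISSING
                dos[male & (dos == 2)] = 1
            pos, ref, alt = normalize_variant(
                variant.POS, variant.REF, variant.ALT[ai]
            )
            rows.append(
                {
                    "chromosome": chrom,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "key": variant_key(chrom, pos, ref, alt),
                    "n_alt_alleles_at_locus": n_alts,
                    "span_nt": max(len(ref), len(alt)),
                    "in_masked_region": position_in_mask(mask, chrom, pos),
                }
            )
            gt_rows.append(dos)
            dp_rows.append(dp)
            gq_rows.append(gq)
            if ad is not None and ad.shape[1] > ai + 1:
                ref_d = ad[:, 0].astype(np.int64)
                alt_d = ad[:, ai + 1].astype(np.int64)
                ref_d = np.where((ref_d < 0) | (ref_d > 2**30), _INT_MISSING, ref_d)
                alt_d = np.where((alt_d < 0) | (alt_d > 2**30), _INT_MISSING, alt_d)
                adr_rows.append(ref_d.astype(np.int32))
                ada_rows.append(alt_d.astype(np.int32))
            else:
                adr_rows.append(np.full(n, _INT_MISSING, dtype=np.int32))
                ada_rows.append(np.full(n, _INT_MISSING, dtype=np.int32))

    variants = pd.DataFrame(rows)
    gt = np.vstack(gt_rows) if gt_rows else np.zeros((0, n), dtype=np.int8)

    # join annotation on the normalized key
    unmatched_ann = annotation.index.difference(variants["key"])
    if len(unmatched_ann):
        raise CohortLoadError(
            f"annotation keys not present in VCF: {sorted(unmatched_ann)[:10]}"
        )
    ann = annotation.reindex(variants["key"])
    variants["gene"] = ann["gene"].to_numpy()
    variants["consequence"] = ann["consequence"].fillna("other").to_numpy()
    variants["maf"] = ann["gnomad_maf"].to_numpy()
    variants["cadd"] = ann["cadd"].to_numpy()
    variants["annotated"] = ~ann["gene"].isna().to_numpy()
    variants.loc[variants["gene"].isin([".", ""]), "gene"] = np.nan

    cohort = Cohort(
        variants=variants,
        gt=gt,
        dp=np.vstack(dp_rows) if dp_rows else np.zeros((0, n), np.int32),
        gq=np.vstack(gq_rows) if gq_rows else np.zeros((0, n), np.int32),
        ad_ref=np.vstack(adr_rows) if adr_rows else np.zeros((0, n), np.int32),
        ad_alt=np.vstack(ada_rows) if ada_rows else np.zeros((0, n), np.int32),
        samples=samples,
        panel=panel,
        pedigree=pedigree,
        deletions=deletions,
        qc_anomalies=pd.DataFrame(anomalies, columns=["sample_id", "variant", "reason"]),
    )
    cohort.recompute_missingness()
    return cohort


# ---------------------------------------------------------------------------
# report writing

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # default float formatting = shortest round-trippable repr, so cached
    # stage outputs reload to bit-identical values (resume support)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_report(
    results: dict[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    metadata: Optional[dict] = None,
) -> list[Path]:
    """Write one TSV per result table plus a JSON run-metadata file.

    Deterministic: identical inputs produce byte-identical TSVs.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create report directory {out}: {e}") from e
    written = []
    for name, df in sorted(results.items()):
        path = out / f"{name}.tsv"
        _write_tsv(df, path)
        written.append(path)
    meta = dict(metadata or {})
    meta.setdefault("versions", _versions())
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(out / "run_metadata.json")
    return written


def _versions() -> dict[str, str]:
    import cyvcf2
    import scipy

    from . import __version__

    return {
        "recburden": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "cyvcf2": cyvcf2.__version__,
    }


# ---------------------------------------------------------------------------
# VCF writing (used by the cohort generator)

def write_vcf(
    path: str | os.PathLike,
    sample_ids: Iterable[str],
    records: Iterable[dict],
    contigs: Iterable[str] = (),
) -> None:
    """Write a minimal VCF 4.2 with GT:DP:GQ:AD format fields.

    Each record dict carries chrom, pos, ref, alt (list of str) and
    ``gt_strings``: an iterable of pre-formatted per-sample FORMAT strings.
    """
    sample_ids = list(sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for rec in records:
            fixed = (
                f"{rec['chrom']}\t{rec['pos']}\t{rec.get('id', '.')}\t{rec['ref']}\t"
                f"{','.join(rec['alt'])}\t.\t.\t.\tGT:DP:GQ:AD\t"
            )
            fh.write(fixed + "\t".join(rec["gt_strings"]) + "\n")
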