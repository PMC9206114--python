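"""Ancestry PCA, KING-robust kinship, and runs-of-homozygosity consanguinity.

All three operate on a dense dosage matrix of common biallelic autosomal
SNVs (variants x samples, int8, -1 missing), the in-memory layout of
:class:`~recburden.model.Cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FilterConfig, kinship_degree

# ---------------------------------------------------------------------------
# PCA


def compute_pca(
    gt: np.ndarray, n_components: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA for ancestry covariates.

    Input sites should be pre-filtered to common, well-called SNVs
    (MAF > 0.01, call rate > 0.99).  Missing genotypes are mean-imputed;
    each site is centered by 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)).
    Returns (scores: n_samples x n_components, explained variance ratio).
    Scores equal the projections onto the leading right-singular directions
    of the standardized matrix, computed via the sample-sample Gram matrix;
    the sign of each component is fixed so its largest-magnitude score is
    positive.
    """
    gt = np.asarray(gt)
    if gt.ndim != 2 or gt.shape[0] == 0:
        raise ValueError("empty genotype matrix")
    X = gt.T.astype(np.float64)  # samples x variants
    miss = X < 0
    X[miss] = np.nan
    p_hat = np.nanmean(X, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    if not keep.any():
        raise ValueError("degenerate genotype matrix")
    X = X[:, keep]
    p_hat = p_hat[keep]
    X = np.where(np.isnan(X), 2.0 * p_hat, X)
    X = (X - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    total_var = float(np.sum(X * X))
    if total_var < 1e-10:
        raise ValueError("degenerate genotype matrix")
    gram = X @ X.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    scores = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    for c in range(k):
        i = int(np.argmax(np.abs(scores[:, c])))
        if scores[i, c] < 0:
            scores[:, c] = -scores[:, c]
    explained = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    if k < n_components:
        scores = np.pad(scores, ((0, 0), (0, n_components - k)))
        explained = np.pad(explained, (0, n_components - k))
    return scores, explained


# ---------------------------------------------------------------------------
# KING-robust kinship


def king_phi_matrix(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs KING-robust kinship.

    phi_hat(i,j) = (N_both_het - 2 N_opposite_hom) / (N_het_i + N_het_j),
    het counts taken over sites non-missing in both samples.  Returns
    (phi matrix, evaluable mask); phi is NaN where the denominator is 0.
    """
    gt = np.asarray(gt)
    het = (gt == 1).astype(np.float32)
    hom_ref = (gt == 0).astype(np.float32)
    hom_alt = (gt == 2).astype(np.float32)
    valid = (gt >= 0).astype(np.float32)
    both_het = het.T @ het
    opp = hom_ref.T @ hom_alt
    opp = opp + opp.T
    het_shared = het.T @ valid  # (i,j): sites het in i, called in j
    denom = het_shared + het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (both_het - 2.0 * opp) / denom
    evaluable = denom > 0
    phi = np.where(evaluable, phi, np.nan)
    return phi.astype(np.float64), evaluable


def king_kinship(
    gt: np.ndarray,
    sample_ids: list[str],
    min_phi: float | None = None,
) -> pd.DataFrame:
    """Pairwise kinship table (upper triangle) with degree labels.

    ``min_phi`` keeps only pairs at or above the threshold (plus
    unevaluable pairs, flagged), which is what relatedness screening needs.
    """
    phi, evaluable = king_phi_matrix(gt)
    n = len(sample_ids)
    iu, ju = np.triu_indices(n, k=1)
    phis = phi[iu, ju]
    ok = evaluable[iu, ju]
    if min_phi is not None:
        keep = (~ok) | (phis >= min_phi)
        iu, ju, phis, ok = iu[keep], ju[keep], phis[keep], ok[keep]
    ids = np.asarray(sample_ids)
    return pd.DataFrame(
        {
            "sample_i": ids[iu],
            "sample_j": ids[ju],
            "phi": phis,
            "degree": [kinship_degree(p) if e else "unevaluable"
                       for p, e in zip(phis, ok)],
            "evaluable": ok,
        }
    )


def unrelated_subset(
    sample_ids: list[str],
    kinship: pd.DataFrame,
    threshold: float = 0.0442,
    cases: set[str] | None = None,
    carriers: set[str] | None = None,
) -> list[str]:
    """Greedy maximal unrelated subset: one removal per related pair.

    Iteratively removes the sample with the most related partners;
    ties are broken by preferring to keep cases, then carriers, then the
    lexicographically smaller ID.  Deterministic.
    """
    cases = cases or set()
    carriers = carriers or set()
    if len(kinship) == 0:
        return list(sample_ids)
    related = kinship[kinship["evaluable"] & (kinship["phi"] >= threshold)]
    adj: dict[str, set[str]] = {s: set() for s in sample_ids}
    for r in related.itertuples(index=False):
        if r.sample_i in adj and r.sample_j in adj:
            adj[r.sample_i].add(r.sample_j)
            adj[r.sample_j].add(r.sample_i)
    removed: set[str] = set()
    while True:
        degrees = {s: len(p - removed) for s, p in adj.items()
                   if s not in removed and len(p - removed) > 0}
        if not degrees:
            break
        max_deg = max(degrees.values())
        candidates = [s for s, d in degrees.items() if d == max_deg]
        # removal preference: non-cases first, then non-carriers,
        # then the lexicographically larger ID
        victim = sorted(
            candidates, key=lambda s: (s in cases, s in carriers, _revlex(s))
        )[0]
        removed.add(victim)
    return [s for s in sample_ids if s not in removed]


def _revlex(s: str) -> tuple:
    """Sort key that orders lexicographically descending."""
    return tuple(-ord(c) for c in s)


# ---------------------------------------------------------------------------
# Runs of homozygosity


@dataclass
class ROHResult:
    segments: pd.DataFrame  # sample_id, chromosome, start, end, n_snps, length_bp
    rates: np.ndarray  # per sample; NaN when undefined
    flags: np.ndarray  # is_consanguineous (rate > threshold); False when undefined
    map_extent_bp: int


def homozygosity_rate(
    gt: np.ndarray,
    chromosomes: np.ndarray,
    positions: np.ndarray,
    sample_ids: list[str],
    config: FilterConfig | None = None,
) -> ROHResult:
    """Sliding-window ROH scan and per-sample autosomal homozygosity rate.

    Input sites must be autosomal SNVs with population MAF > 0.05, sorted
    by position within chromosome.  Windows of ``roh_window_snps``
    consecutive SNVs qualify with at most 1 heterozygote and 5 missing
    calls; a SNV enters a run when at least 5% of the windows covering it
    qualify; maximal runs of at least 100 SNVs and 1,000 kb are emitted.
    The rate is total run length over the total extent of the SNV map
    (per-chromosome max minus min position, summed); a sample set with
    fewer mapped SNVs than one window has an undefined (NaN) rate.
    """
    config = config or FilterConfig()
    w = config.roh_window_snps
    gt = np.asarray(gt)
    n_samples = gt.shape[1]
    chromosomes = np.asarray(chromosomes).astype(str)
    positions = np.asarray(positions)

    extent = 0
    seg_rows: list[dict] = []
    total_len = np.zeros(n_samples, dtype=np.int64)

    if gt.shape[0] < w:
        return ROHResult(
            segments=pd.DataFrame(
                columns=["sample_id", "chromosome", "start", "end", "n_snps", "length_bp"]
            ),
            rates=np.full(n_samples, np.nan),
            flags=np.zeros(n_samples, dtype=bool),
            map_extent_bp=0,
        )

    for chrom in pd.unique(chromosomes):
        sel = chromosomes == chrom
        pos = positions[sel]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        sub = gt[sel][order]
        m = len(pos)
        extent += int(pos.max() - pos.min()) if m else 0
        if m < w:
            continue
        het = (sub == 1).astype(np.int32)
        miss = (sub < 0).astype(np.int32)
        cs_het = np.vstack([np.zeros((1, n_samples), np.int32), np.cumsum(het, axis=0)])
        cs_mis = np.vstack([np.zeros((1, n_samples), np.int32), np.cumsum(miss, axis=0)])
        win_het = cs_het[w:] - cs_het[:-w]
        win_mis = cs_mis[w:] - cs_mis[:-w]
        win_ok = (
            (win_het <= config.roh_window_max_het)
            & (win_mis <= config.roh_window_max_missing)
        ).astype(np.int32)
        n_win = m - w + 1
        cs_ok = np.vstack([np.zeros((1, n_samples), np.int32), np.cumsum(win_ok, axis=0)])
        # windows covering SNP i: indices max(0, i-w+1) .. min(i, n_win-1)
        lo = np.maximum(0, np.arange(m) - w + 1)
        hi = np.minimum(np.arange(m), n_win - 1)
        n_cover = (hi - lo + 1).astype(np.float64)
        ok_cover = cs_ok[hi + 1] - cs_ok[lo]
        frac = ok_cover / n_cover[:, None]
        eligible = frac >= config.roh_hit_fraction

        for s in range(n_samples):
            idx = np.flatnonzero(eligible[:, s])
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [idx.size - 1]])
            for a, b in zip(starts, ends):
                i0, i1 = idx[a], idx[b]
                n_snps = i1 - i0 + 1
                length = int(pos[i1] - pos[i0] + 1)
                if (
                    n_snps >= config.roh_min_segment_snps
                    and length >= config.roh_min_segment_kb * 1000
                ):
                    seg_rows.append(
                        {
                            "sample_id": sample_ids[s],
                            "chromosome": chrom,
                            "start": int(pos[i0]),
                            "end": int(pos[i1]),
                            "n_snps": int(n_snps),
                            "length_bp": length,
                        }
                    )
                    total_len[s] += length

    rates = total_len / extent if extent > 0 else np.full(n_samples, np.nan)
    flags = np.where(np.isnan(rates), False, rates > config.consanguinity_threshold)
    return ROHResult(
        segments=pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chromosome", "start", "end", "n_snps", "length_bp"],
        ),
        rates=np.asarray(rates, dtype=float),
        flags=flags.astype(bool),
        map_extent_bp=int(extent),
    )
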