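"""Ancestry PCA, KING-robust kinship, unrelated-subset pruning, and the
runs-of-homozygosity scan, validated on simulated genotypes with known
structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recburden.model import FilterConfig, kinship_degree
from recburden.relatedness import (
    compute_pca,
    homozygosity_rate,
    king_kinship,
    king_phi_matrix,
    unrelated_subset,
)
from recburden.simulate import balding_nichols


def two_pop_genotypes(rng, n_per_pop=100, n_snps=2000, fst=0.1):
    p_anc = rng.uniform(0.2, 0.5, size=n_snps)
    freqs = balding_nichols(rng, p_anc, 2, fst)
    pops = np.r_[np.zeros(n_per_pop, int), np.ones(n_per_pop, int)]
    gt = rng.binomial(2, freqs[:, pops]).astype(np.int8)
    return gt, pops


class TestPCA:
    def test_pc1_separates_two_populations(self, rng):
        gt, pops = two_pop_genotypes(rng)
        scores, explained = compute_pca(gt)
        pc1 = scores[:, 0]
        a, b = pc1[pops == 0], pc1[pops == 1]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            max(b.min(), a.min()) > min(b.max(), a.max())
        # no overlap of within-group ranges
        assert (a.max() < b.min()) or (b.max() < a.min())
        assert explained[0] > explained[1]

    def test_scores_orthogonal(self, rng):
        gt, _ = two_pop_genotypes(rng, n_per_pop=50, n_snps=500)
        scores, _ = compute_pca(gt)
        norm = scores / np.linalg.norm(scores, axis=0)
        off = norm.T @ norm - np.eye(scores.shape[1])
        assert np.abs(off).max() < 1e-8

    def test_permutation_invariance(self, rng):
        gt, _ = two_pop_genotypes(rng, n_per_pop=40, n_snps=400)
        scores, _ = compute_pca(gt)
        perm = rng.permutation(gt.shape[1])
        scores_p, _ = compute_pca(gt[:, perm])
        for k in range(scores.shape[1]):
            col = scores[perm, k]
            assert np.allclose(col, scores_p[:, k], atol=1e-6) or \
                np.allclose(col, -scores_p[:, k], atol=1e-6)

    def test_duplicated_genotype_vector_degenerate(self):
        gt = np.tile(np.array([[1], [0], [2]], dtype=np.int8), (1, 10))
        with pytest.raises(ValueError, match="degenerate"):
            compute_pca(gt)

    def test_missing_genotypes_mean_imputed(self, rng):
        gt, pops = two_pop_genotypes(rng, n_per_pop=50, n_snps=800)
        gt_miss = gt.copy()
        mask = rng.random(gt.shape) < 0.02
        gt_miss[mask] = -1
        scores, _ = compute_pca(gt_miss)
        pc1 = scores[:, 0]
        assert (pc1[pops == 0].max() < pc1[pops == 1].min()) or \
            (pc1[pops == 1].max() < pc1[pops == 0].min())


def related_pair(rng, freqs, gamma):
    """Genotype pair sharing one haplotype copy with probability gamma."""
    a1 = rng.random(len(freqs)) < freqs
    a2 = rng.random(len(freqs)) < freqs
    b1 = rng.random(len(freqs)) < freqs
    b2 = rng.random(len(freqs)) < freqs
    donor = np.where(rng.random(len(freqs)) < 0.5, a1, a2)
    take = rng.random(len(freqs)) < gamma
    b1 = np.where(take, donor, b1)
    ga = a1.astype(np.int8) + a2.astype(np.int8)
    gb = b1.astype(np.int8) + b2.astype(np.int8)
    return ga, gb


class TestKing:
    def test_identical_genotypes_phi_half(self):
        gt = np.array([[1, 1], [0, 0], [2, 2], [1, 1]], dtype=np.int8)
        phi, ok = king_phi_matrix(gt)
        assert ok[0, 1]
        assert phi[0, 1] == pytest.approx(0.5)
        assert phi[0, 0] == pytest.approx(0.5)  # self-kinship >= 0.354

    def test_symmetry(self, rng):
        gt = rng.integers(0, 3, size=(200, 8)).astype(np.int8)
        phi, _ = king_phi_matrix(gt)
        assert np.allclose(phi, phi.T, equal_nan=True)

    def test_no_het_pair_unevaluable(self):
        gt = np.array([[0, 2], [2, 0], [0, 0]], dtype=np.int8)
        table = king_kinship(gt, ["A", "B"])
        assert list(table["degree"]) == ["unevaluable"]

    def test_parent_offspring_mean_phi(self, rng):
        freqs = rng.uniform(0.05, 0.5, size=10_000)
        phis = []
        for _ in range(30):
            ga, gb = related_pair(rng, freqs, 1.0)  # parent-offspring-like
            phi, _ = king_phi_matrix(np.column_stack([ga, gb]))
            phis.append(phi[0, 1])
        assert np.mean(phis) == pytest.approx(0.25, abs=0.02)

    def test_cross_population_unrelated_below_threshold(self, rng):
        # modest divergence: the robust estimator stays within the
        # unrelated band for cross-population pairs
        p_anc = rng.uniform(0.2, 0.5, size=10_000)
        freqs = balding_nichols(rng, p_anc, 2, fst=0.02)
        hits = 0
        n_pairs = 200
        for _ in range(n_pairs):
            ga = rng.binomial(2, freqs[:, 0]).astype(np.int8)
            gb = rng.binomial(2, freqs[:, 1]).astype(np.int8)
            phi, _ = king_phi_matrix(np.column_stack([ga, gb]))
            hits += abs(phi[0, 1]) < 0.0442
        assert hits / n_pairs >= 0.99

    def test_degree_thresholds(self):
        assert kinship_degree(0.40) == "duplicate_MZ"
        assert kinship_degree(0.25) == "first"
        assert kinship_degree(0.125) == "second"
        assert kinship_degree(0.0442) == "third"
        assert kinship_degree(0.0441) == "unrelated"


def pairs_frame(pairs):
    return pd.DataFrame(
        [{"sample_i": a, "sample_j": b, "phi": p, "degree": "x",
          "evaluable": True} for a, b, p in pairs]
    )


class TestUnrelatedSubset:
    def test_no_related_pairs_identity(self):
        kept = unrelated_subset(["a", "b", "c"], pairs_frame([]))
        assert kept == ["a", "b", "c"]

    def test_one_removal_per_pair(self):
        kin = pairs_frame([("a", "b", 0.2), ("c", "d", 0.3)])
        kept = unrelated_subset(["a", "b", "c", "d"], kin)
        assert len(kept) == 2
        assert ("a" in kept) != ("b" in kept)
        assert ("c" in kept) != ("d" in kept)

    def test_chain_removes_shared_member(self):
        kin = pairs_frame([("a", "b", 0.2), ("b", "c", 0.2)])
        assert unrelated_subset(["a", "b", "c"], kin) == ["a", "c"]

    def test_tie_break_prefers_cases_then_carriers_then_lexicographic(self):
        kin = pairs_frame([("a", "b", 0.2)])
        assert unrelated_subset(["a", "b"], kin, cases={"b"}) == ["b"]
        assert unrelated_subset(["a", "b"], kin, carriers={"b"}) == ["b"]
        assert unrelated_subset(["a", "b"], kin) == ["a"]

    def test_below_threshold_pairs_ignored(self):
        kin = pairs_frame([("a", "b", 0.02)])
        assert unrelated_subset(["a", "b"], kin) == ["a", "b"]


def dense_map(n_snps=5000, spacing=20_000):
    """Single-chromosome SNV map at one SNP per 20 kb (100 Mb total)."""
    pos = np.arange(1, n_snps + 1) * spacing
    chrom = np.repeat("1", n_snps)
    return chrom, pos


class TestROH:
    def make_gt(self, rng, n_snps, hom_blocks, n_samples=1):
        """Heterozygosity ~50% outside planted homozygous blocks."""
        gt = rng.choice([0, 1, 1, 2], size=(n_snps, n_samples)).astype(np.int8)
        for (lo, hi), s in hom_blocks:
            gt[lo:hi, s] = rng.choice([0, 2], size=hi - lo)
        return gt

    def test_planted_block_recovered_and_rate_flagged(self, rng):
        chrom, pos = dense_map()
        # 30 Mb block (1500 SNPs) on a ~100 Mb map -> rate ~ 0.30
        gt = self.make_gt(rng, 5000, [((1000, 2500), 0)])
        res = homozygosity_rate(gt, chrom, pos, ["S0"])
        assert len(res.segments) == 1
        seg = res.segments.iloc[0]
        planted_lo, planted_hi = 1001 * 20_000, 2500 * 20_000
        overlap = min(seg.end, planted_hi) - max(seg.start, planted_lo)
        assert overlap / (planted_hi - planted_lo) >= 0.9  # recall by length
        assert res.rates[0] > 0.01 and res.flags[0]

    def test_all_heterozygous_sample_clean(self, rng):
        chrom, pos = dense_map(2000)
        gt = np.ones((2000, 1), dtype=np.int8)
        res = homozygosity_rate(gt, chrom, pos, ["S0"])
        assert len(res.segments) == 0
        assert res.rates[0] == 0.0 and not res.flags[0]

    def test_short_blocks_below_segment_thresholds_ignored(self, rng):
        chrom, pos = dense_map()
        # 50-SNP block (1 Mb) passes the window rule but fails the
        # 100-SNP / 1,000-kb segment thresholds jointly (needs 100 snps)
        gt = self.make_gt(rng, 5000, [((1000, 1050), 0)])
        res = homozygosity_rate(gt, chrom, pos, ["S0"])
        assert len(res.segments) == 0

    def test_fewer_snps_than_window_rate_undefined(self, rng):
        chrom, pos = dense_map(30)
        gt = np.zeros((30, 2), dtype=np.int8)
        res = homozygosity_rate(gt, chrom, pos, ["S0", "S1"])
        assert np.isnan(res.rates).all()
        assert not res.flags.any()

    def test_recall_by_length_for_blocks_over_2mb(self, rng):
        chrom, pos = dense_map(5000)
        blocks = [((200, 350), 0), ((1000, 1500), 0), ((3000, 4000), 0)]
        gt = self.make_gt(rng, 5000, blocks)
        res = homozygosity_rate(gt, chrom, pos, ["S0"])
        planted = sum((hi - lo) * 20_000 for (lo, hi), _ in blocks)
        recovered = 0
        for (lo, hi), _ in blocks:
            lo_bp, hi_bp = (lo + 1) * 20_000, hi * 20_000
            for seg in res.segments.itertuples(index=False):
                recovered += max(0, min(seg.end, hi_bp) - max(seg.start, lo_bp))
        assert recovered / planted >= 0.9
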