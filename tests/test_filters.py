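"""Genotype/site QC rules and candidate-variant selection, including the
stated boundary behavior and the monotonicity/idempotence invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recburden.filters import (
    apply_genotype_filters,
    apply_site_filters,
    select_candidate_variants,
)
from recburden.model import FilterConfig, GenePanelEntry

from conftest import make_cohort, sample_row, variant_row

PANEL = {
    "G1": GenePanelEntry("G1", "1", 20.0, "AR"),
    "GX": GenePanelEntry("GX", "X", 20.0, "XR"),
}


def qc_cohort(gt, dp, gq, ad):
    """One autosomal site, n samples with explicit QC fields."""
    n = len(gt)
    return make_cohort(
        [variant_row("1", 100, gene="G1")],
        np.array([gt], dtype=np.int8),
        [sample_row(f"S{i}") for i in range(n)],
        panel=PANEL,
        dp=np.array([dp]), gq=np.array([gq]),
        ad_ref=np.array([[a[0] for a in ad]]),
        ad_alt=np.array([[a[1] for a in ad]]),
    )


class TestGenotypeFilters:
    @pytest.mark.parametrize(
        "gt,dp,gq,ad,kept,reason",
        [
            (1, 7, 60, (15, 15), False, "low_depth"),  # coverage < 8x
            (1, 30, 19, (15, 15), False, "low_gq"),  # GQ < 20
            (1, 30, 99, (10, 3), True, None),  # ratio 3/13 = 0.231 >= 0.20
            (1, 30, 99, (10, 2), False, "low_minor_read_ratio"),  # 2/12 < 0.20
            (1, 8, 20, (4, 4), True, None),  # boundary: strict "<" thresholds
            (2, 30, 99, (0, 30), True, None),  # homozygote exempt from ratio
            (2, 30, 99, (28, 2), True, None),  # even unbalanced homozygote
            (1, 30, 99, (-1, -1), False, "ad_absent_het"),  # AD missing on het
        ],
    )
    def test_single_call_rules(self, gt, dp, gq, ad, kept, reason):
        cohort = qc_cohort([gt], [dp], [gq], [ad])
        log = apply_genotype_filters(cohort)
        assert (cohort.gt[0, 0] >= 0) == kept
        if reason:
            assert reason in set(log["reason"])

    def test_hemizygous_male_exempt_from_ratio_rule(self):
        cohort = make_cohort(
            [variant_row("X", 500, gene="GX")],
            np.array([[1]], dtype=np.int8),
            [sample_row("S0", sex="male")],
            panel=PANEL,
            ad_ref=np.array([[28]]), ad_alt=np.array([[2]]),
        )
        apply_genotype_filters(cohort)
        assert cohort.gt[0, 0] == 1

    def test_failure_reasons_counted(self):
        cohort = qc_cohort([1, 1, 1], [7, 7, 30], [99, 99, 10], [(15, 15)] * 3)
        log = apply_genotype_filters(cohort)
        counts = log["reason"].value_counts()
        assert counts["low_depth"] == 2 and counts["low_gq"] == 1

    def test_idempotent(self, rng):
        gt = rng.integers(-1, 3, size=(5, 8)).astype(np.int8)
        dp = rng.integers(0, 40, size=(5, 8))
        gq = rng.integers(0, 99, size=(5, 8))
        cohort = qc_cohort([0], [30], [99], [(30, 0)])  # placeholder
        cohort = make_cohort(
            [variant_row("1", 100 + i, gene="G1") for i in range(5)],
            gt, [sample_row(f"S{i}") for i in range(8)], panel=PANEL,
            dp=dp, gq=gq,
        )
        apply_genotype_filters(cohort)
        once = cohort.gt.copy()
        log2 = apply_genotype_filters(cohort)
        assert np.array_equal(cohort.gt, once)
        assert len(log2) == 0


class TestSiteFilters:
    def make(self, **kw):
        row = variant_row("1", 100, gene="G1")
        row.update(kw)
        return make_cohort(
            [row], np.array([[1, 1]], dtype=np.int8),
            [sample_row("S0"), sample_row("S1")], panel=PANEL,
        )

    @pytest.mark.parametrize(
        "field,value,kept",
        [
            ("n_alt_alleles_at_locus", 4, True),
            ("n_alt_alleles_at_locus", 5, False),  # more than four alleles
            ("span_nt", 15, True),  # boundary: strict ">"
            ("span_nt", 16, False),
            ("in_masked_region", True, False),
        ],
    )
    def test_single_site_rules(self, field, value, kept):
        cohort = self.make(**{field: value})
        filtered, log = apply_site_filters(cohort)
        assert (filtered.n_variants == 1) == kept

    def test_missingness_recomputed_after_genotype_filters(self):
        # 2 of 10 genotypes fail depth -> missingness 0.2 > 0.10 -> dropped
        cohort = make_cohort(
            [variant_row("1", 100, gene="G1")],
            np.ones((1, 10), dtype=np.int8),
            [sample_row(f"S{i}") for i in range(10)], panel=PANEL,
            dp=np.array([[7, 7] + [30] * 8]),
        )
        apply_genotype_filters(cohort)
        filtered, log = apply_site_filters(cohort)
        assert filtered.n_variants == 0
        assert set(log["reason"]) == {"high_missingness"}

    def test_idempotent(self):
        cohort = self.make(span_nt=16)
        f1, _ = apply_site_filters(cohort)
        f2, log2 = apply_site_filters(f1)
        assert f2.n_variants == f1.n_variants and len(log2) == 0

    def test_tightening_thresholds_monotone(self, rng):
        variants = [
            variant_row("1", 100 + i, gene="G1",
                        span_nt=int(rng.integers(1, 30)),
                        n_alt_alleles_at_locus=int(rng.integers(1, 8)))
            for i in range(40)
        ]
        gt = rng.integers(-1, 3, size=(40, 10)).astype(np.int8)
        samples = [sample_row(f"S{i}") for i in range(10)]
        loose, _ = apply_site_filters(
            make_cohort(variants, gt, samples, panel=PANEL), FilterConfig())
        tight, _ = apply_site_filters(
            make_cohort(variants, gt, samples, panel=PANEL),
            FilterConfig(max_span_nt=10, max_alt_alleles=2,
                         max_site_missingness=0.05))
        assert set(tight.variants["key"]) <= set(loose.variants["key"])


class TestCandidateSelection:
    def variants(self):
        return [
            # missense, rare, CADD above MSC -> primary
            variant_row("1", 1, gene="G1", consequence="missense",
                        maf=5e-5, cadd=25.0),
            # too common for the primary set
            variant_row("1", 2, gene="G1", consequence="missense",
                        maf=2e-4, cadd=25.0),
            # pLOF, common: only the MAF-unrestricted pLOF set
            variant_row("1", 3, gene="G1", consequence="pLOF",
                        maf=2e-3, cadd=40.0),
            # pLOF, rare, high CADD: in primary and both pLOF sets
            variant_row("1", 4, gene="G1", consequence="pLOF",
                        maf=1e-5, cadd=40.0),
            # rare synonymous: negative-control set only (no CADD rule)
            variant_row("1", 5, gene="G1", consequence="synonymous",
                        maf=5e-5, cadd=1.0),
            # CADD at/below the gene MSC: excluded under the strict rule
            variant_row("1", 6, gene="G1", consequence="missense",
                        maf=5e-5, cadd=20.0),
        ]

    def select(self, config=None):
        import pandas as pd

        vdf = make_cohort(
            self.variants(), np.zeros((6, 1), dtype=np.int8),
            [sample_row("S0")], panel=PANEL,
        ).variants
        return select_candidate_variants(vdf, PANEL, config), vdf

    def test_class_membership(self):
        sets, vdf = self.select()
        key = vdf.set_index("position")["key"]
        assert sets.primary_set == {key[1], key[4]}
        assert sets.plof_set == {key[4]}
        assert sets.plof_any_maf_set == {key[3], key[4]}
        assert sets.synonymous_control_set == {key[5]}

    def test_set_invariants(self):
        sets, _ = self.select()
        assert sets.plof_set <= sets.primary_set
        assert not (sets.synonymous_control_set & sets.primary_set)

    def test_msc_boundary_flag(self):
        sets_ge, vdf = self.select(FilterConfig(cadd_strictly_greater=False))
        key = vdf.set_index("position")["key"]
        assert key[6] in sets_ge.primary_set  # cadd == msc passes under >=

    def test_unknown_gene_rejected(self):
        import pandas as pd

        vdf = make_cohort(
            [variant_row("1", 1, gene="NOT_IN_PANEL", consequence="missense",
                         maf=0.0, cadd=30.0)],
            np.zeros((1, 1), dtype=np.int8), [sample_row("S0")], panel=PANEL,
        ).variants
        with pytest.raises(ValueError, match="NOT_IN_PANEL"):
            select_candidate_variants(vdf, PANEL)
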