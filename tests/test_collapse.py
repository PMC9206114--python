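"""Recessive collapsing: mechanisms, trio phasing, precedence, the
order/batch invariances, and familial segregation checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from recburden.collapse import carriers, check_segregation, collapse_recessive
from recburden.model import DeletionCall, GenePanelEntry

from conftest import make_cohort, sample_row, variant_row

PANEL = {
    "G1": GenePanelEntry("G1", "1", 20.0, "AR"),
    "GX": GenePanelEntry("GX", "X", 20.0, "XR"),
}


def trio_ped(child="C", father="F", mother="M", child_sex=1):
    return pd.DataFrame({
        "family_id": ["FAM"] * 3,
        "sample_id": [child, father, mother],
        "father_id": [father, "0", "0"],
        "mother_id": [mother, "0", "0"],
        "sex": [child_sex, 1, 2],
        "phenotype": [2, 1, 1],
    })


def autosomal_pair_cohort(child, father, mother, pedigree=None):
    """Two qualifying G1 sites; genotypes given as (site_a, site_b) dosages."""
    gt = np.array([
        [child[0], father[0], mother[0]],
        [child[1], father[1], mother[1]],
    ], dtype=np.int8)
    return make_cohort(
        [variant_row("1", 100, gene="G1"), variant_row("1", 200, gene="G1")],
        gt,
        [sample_row("C", group="case", severity="critical"),
         sample_row("F", sex="male"), sample_row("M")],
        panel=PANEL, pedigree=pedigree,
    )


ALL_KEYS = {"1:100:A:G", "1:200:A:G", "X:500:A:G"}


class TestMechanisms:
    def test_male_hemizygous_x(self):
        cohort = make_cohort(
            [variant_row("X", 500, gene="GX")],
            np.array([[1, 1]], dtype=np.int8),
            [sample_row("B", sex="male", group="case"),
             sample_row("G", sex="female")],
            panel=PANEL,
        )
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        assert [(c.sample_id, c.mechanism) for c in calls] == [("B", "hemizygous")]
        # the female heterozygote is not a carrier

    def test_female_single_het_not_a_carrier(self):
        cohort = autosomal_pair_cohort((1, 0), (0, 0), (0, 0))
        assert collapse_recessive(cohort, ALL_KEYS, "primary") == []

    def test_homozygote(self):
        cohort = autosomal_pair_cohort((2, 0), (1, 0), (1, 0))
        (call,) = collapse_recessive(cohort, ALL_KEYS, "primary")
        assert call.mechanism == "homozygous"
        assert call.variant_keys == ("1:100:A:G",)

    def test_compound_het_potential_without_pedigree(self):
        cohort = autosomal_pair_cohort((1, 1), (0, 0), (0, 0))
        (call,) = collapse_recessive(cohort, ALL_KEYS, "primary")
        assert call.mechanism == "compound_het_potential"
        assert len(call.variant_keys) == 2

    def test_trio_confirms_trans(self):
        # father het site A only, mother het site B only -> trans
        cohort = autosomal_pair_cohort((1, 1), (1, 0), (0, 1), trio_ped())
        (call,) = collapse_recessive(cohort, ALL_KEYS, "primary")
        assert call.mechanism == "compound_het_confirmed"

    def test_trio_refutes_cis(self):
        # both variants from the father, absent in the mother -> cis; the
        # child gets no call (the double-het father is himself a potential
        # compound het, which is expected)
        cohort = autosomal_pair_cohort((1, 1), (1, 1), (0, 0), trio_ped())
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        assert "C" not in carriers(calls)

    def test_ambiguous_parents_stay_potential(self):
        cohort = autosomal_pair_cohort((1, 1), (1, 1), (1, 1), trio_ped())
        calls = [c for c in collapse_recessive(cohort, ALL_KEYS, "primary")
                 if c.sample_id == "C"]
        assert [c.mechanism for c in calls] == ["compound_het_potential"]

    def test_homozygous_deletion_from_deletion_calls(self):
        cohort = autosomal_pair_cohort((0, 0), (0, 0), (0, 0))
        calls = collapse_recessive(
            cohort, ALL_KEYS, "primary",
            deletions=[DeletionCall("C", "G1", "1", 50, 5000)])
        assert [(c.sample_id, c.mechanism) for c in calls] == \
            [("C", "homozygous_deletion")]

    def test_strongest_mechanism_wins(self):
        # homozygous at one site AND het at two -> one homozygous call
        gt = np.array([[2], [1], [1]], dtype=np.int8)
        cohort = make_cohort(
            [variant_row("1", p, gene="G1") for p in (100, 200, 300)],
            gt, [sample_row("C")], panel=PANEL,
        )
        keys = {"1:100:A:G", "1:200:A:G", "1:300:A:G"}
        (call,) = collapse_recessive(cohort, keys, "primary")
        assert call.mechanism == "homozygous"

    def test_deletion_copy_number_validated(self):
        with pytest.raises(ValueError, match="copy_number"):
            DeletionCall("C", "G1", "1", 50, 5000, copy_number=1)

    def test_unknown_pedigree_sample_rejected(self):
        ped = trio_ped(father="GHOST")
        cohort = autosomal_pair_cohort((1, 1), (0, 0), (0, 0))
        cohort.pedigree = ped
        with pytest.raises(ValueError, match="GHOST"):
            collapse_recessive(cohort, ALL_KEYS, "primary")


class TestInvariances:
    def build(self, rng, order=None):
        variants = [variant_row("1", p, gene="G1") for p in (100, 200, 300)]
        gt = rng.integers(0, 3, size=(3, 12)).astype(np.int8)
        if order is not None:
            variants = [variants[i] for i in order]
            gt = gt[list(order)]
        return make_cohort(
            variants, gt, [sample_row(f"S{i}") for i in range(12)], panel=PANEL)

    def test_carrier_status_invariant_to_variant_order(self, rng):
        keys = {f"1:{p}:A:G" for p in (100, 200, 300)}
        base = carriers(collapse_recessive(self.build(
            np.random.default_rng(5)), keys, "primary"))
        shuffled = carriers(collapse_recessive(self.build(
            np.random.default_rng(5), order=(2, 0, 1)), keys, "primary"))
        assert base == shuffled

    def test_carrier_status_invariant_to_batching(self):
        rng = np.random.default_rng(5)
        cohort = self.build(rng)
        keys = {f"1:{p}:A:G" for p in (100, 200, 300)}
        whole = carriers(collapse_recessive(cohort, keys, "primary"))
        halves = set()
        for cols in (range(6), range(6, 12)):
            cols = list(cols)
            sub = make_cohort(
                [variant_row("1", p, gene="G1") for p in (100, 200, 300)],
                cohort.gt[:, cols],
                [sample_row(f"S{i}") for i in cols], panel=PANEL)
            halves |= carriers(collapse_recessive(sub, keys, "primary"))
        assert whole == halves

    def test_removing_a_variant_never_creates_a_carrier(self):
        cohort = self.build(np.random.default_rng(5))
        keys = {f"1:{p}:A:G" for p in (100, 200, 300)}
        full = carriers(collapse_recessive(cohort, keys, "primary"))
        for k in keys:
            reduced = carriers(collapse_recessive(cohort, keys - {k}, "primary"))
            assert reduced <= full


class TestSegregation:
    def test_textbook_recessive_trio_consistent(self):
        ped = trio_ped()
        cohort = autosomal_pair_cohort((2, 0), (1, 0), (1, 0), ped)
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        report = check_segregation(ped, cohort, "G1", calls)
        assert report["FAM"]["consistent"]
        assert report["FAM"]["genotype_positive_unaffected"] == []

    def test_mendelian_violation_reported(self):
        ped = trio_ped()
        # homozygous child but the father carries zero alleles
        cohort = autosomal_pair_cohort((2, 0), (0, 0), (1, 0), ped)
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        report = check_segregation(ped, cohort, "G1", calls)
        assert not report["FAM"]["consistent"]
        assert "zero alleles" in report["FAM"]["inconsistencies"][0]

    def test_unaffected_hemizygous_sibling_is_penetrance_not_inconsistency(self):
        # proband and younger sibling share the hemizygous genotype; the
        # sibling stayed asymptomatic -> consistent, listed once
        ped = pd.DataFrame({
            "family_id": ["FAM"] * 4,
            "sample_id": ["P", "SIB", "F", "M"],
            "father_id": ["F", "F", "0", "0"],
            "mother_id": ["M", "M", "0", "0"],
            "sex": [1, 1, 1, 2],
            "phenotype": [2, 1, 1, 1],
        })
        gt = np.array([[1, 1, 0, 1]], dtype=np.int8)  # X site: P, SIB, F, M
        cohort = make_cohort(
            [variant_row("X", 500, gene="GX")], gt,
            [sample_row("P", sex="male", group="case", severity="critical"),
             sample_row("SIB", sex="male"), sample_row("F", sex="male"),
             sample_row("M")],
            panel=PANEL, pedigree=ped,
        )
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        report = check_segregation(ped, cohort, "GX", calls)
        assert report["FAM"]["consistent"]
        assert report["FAM"]["genotype_positive_unaffected"] == ["SIB"]

    def test_hemizygote_mother_must_carry(self):
        ped = trio_ped()
        gt = np.array([[1, 0, 0]], dtype=np.int8)  # mother carries nothing
        cohort = make_cohort(
            [variant_row("X", 500, gene="GX")], gt,
            [sample_row("C", sex="male", group="case"),
             sample_row("F", sex="male"), sample_row("M")],
            panel=PANEL, pedigree=ped,
        )
        calls = collapse_recessive(cohort, ALL_KEYS, "primary")
        report = check_segregation(ped, cohort, "GX", calls)
        assert not report["FAM"]["consistent"]
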