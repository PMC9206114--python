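"""Burden testing and cohort summary statistics.

The burden test compares the proportion of cases and controls carrying at
least one qualifying recessive genotype across the gene panel, with a
Firth-penalized logistic regression of case status on carrier status,
optionally adjusted for sex and the first five ancestry principal
components.  P-values come from the penalized likelihood-ratio test;
confidence intervals from the profile penalized likelihood.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._util import percent, round_half_up
from .firth import firth_fit, firth_inference
from .model import BurdenResult, RecessiveCall

AUTOSOMAL_MECHANISMS = (
    "homozygous",
    "homozygous_deletion",
    "compound_het_confirmed",
    "compound_het_potential",
)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities no larger than the observed
    table's, with margins fixed.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    return float(sp_stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _design(
    samples: pd.DataFrame,
    carrier: np.ndarray,
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(samples)), carrier.astype(float)]
    names = ["intercept", "carrier"]
    for cov in covariates:
        if cov == "sex":
            cols.append((samples["sex"] == "male").to_numpy(dtype=float))
        else:
            cols.append(samples[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def burden_test(
    samples: pd.DataFrame,
    calls: Iterable[RecessiveCall],
    variant_set_label: str,
    covariates: Sequence[str] = ("sex", "PC1", "PC2", "PC3", "PC4", "PC5"),
    gene_subset: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> BurdenResult:
    """Firth-penalized carrier burden test of case vs control status.

    ``samples`` must carry sex and any requested PC columns; ``calls`` are
    the collapsed recessive genotypes for the tested variant set.  With a
    constant carrier indicator the result degrades to p = 1 with a warning
    rather than failing.
    """
    calls = [c for c in calls if c.variant_set_label == variant_set_label]
    if gene_subset is not None:
        genes = set(gene_subset)
        calls = [c for c in calls if c.gene in genes]
    carrier_ids = {c.sample_id for c in calls}
    carrier = samples["sample_id"].isin(carrier_ids).to_numpy()
    case = (samples["group"] == "case").to_numpy()

    cc = int((carrier & case).sum())
    cn = int(case.sum())
    kc = int((carrier & ~case).sum())
    kn = int((~case).sum())

    if carrier.all() or not carrier.any():
        return BurdenResult(
            variant_set_label=variant_set_label,
            carriers_cases=cc, n_cases=cn, carriers_controls=kc, n_controls=kn,
            odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan, p_value=1.0,
            covariates_used=tuple(covariates),
            gene_subset=tuple(gene_subset) if gene_subset else None,
            warning="constant carrier indicator",
        )

    X, _names = _design(samples, carrier, covariates)
    fit = firth_fit(X, case.astype(float))
    p, lo, hi, warning = firth_inference(fit, X, case.astype(float), 1, alpha=alpha)
    return BurdenResult(
        variant_set_label=variant_set_label,
        carriers_cases=cc, n_cases=cn, carriers_controls=kc, n_controls=kn,
        odds_ratio=float(np.exp(fit.beta[1])),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)), p_value=p,
        covariates_used=tuple(covariates),
        gene_subset=tuple(gene_subset) if gene_subset else None,
        warning=warning,
    )


def burden_results_frame(results: Iterable[BurdenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "variant_set_label": r.variant_set_label,
            "gene_subset": ";".join(r.gene_subset) if r.gene_subset else "all",
            "carriers_cases": r.carriers_cases, "n_cases": r.n_cases,
            "carriers_controls": r.carriers_controls, "n_controls": r.n_controls,
            "odds_ratio": r.odds_ratio, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p_value": r.p_value,
            "covariates": ";".join(r.covariates_used),
            "warning": r.warning or "",
        })
    return pd.DataFrame(rows, columns=[
        "variant_set_label", "gene_subset", "carriers_cases", "n_cases",
        "carriers_controls", "n_controls", "odds_ratio", "ci_low", "ci_high",
        "p_value", "covariates", "warning",
    ]).sort_values(["gene_subset", "variant_set_label"]).reset_index(drop=True)


def cohort_summary(
    samples: pd.DataFrame,
    calls: Iterable[RecessiveCall],
    unrelated_patients: Sequence[str],
    variant_set_label: str = "primary",
) -> dict:
    """The reported cohort proportions, rounded half-up at report precision.

    ``samples`` must carry an ``is_consanguineous`` boolean column (from
    the ROH stage); ``unrelated_patients`` is the kinship-pruned patient
    subset.  Returns carrier percentages overall / unrelated / by
    inheritance mode / by sex / by severity, consanguinity rates, the
    consanguinity-by-status and carrier-by-consanguinity Fisher tests, and
    the case male:female ratio.
    """
    calls = [c for c in calls if c.variant_set_label == variant_set_label]
    carrier_ids = {c.sample_id for c in calls}
    ar_ids = {c.sample_id for c in calls if c.mechanism in AUTOSOMAL_MECHANISMS}
    xr_ids = {c.sample_id for c in calls if c.mechanism == "hemizygous"}

    case = samples[samples["group"] == "case"]
    ctrl = samples[samples["group"] == "control"]
    case_ids = set(case["sample_id"])
    boys = case[case["sex"] == "male"]
    unrel = set(unrelated_patients) & case_ids
    unrel_df = case[case["sample_id"].isin(unrel)]
    unrel_critical = unrel_df[unrel_df["severity"] == "critical"]

    cons = samples.set_index("sample_id")["is_consanguineous"].astype(bool)
    cons_case = int(cons.loc[list(case_ids)].sum())
    cons_ctrl = int(cons.loc[ctrl["sample_id"]].sum())

    carriers_cases = len(carrier_ids & case_ids)
    carriers_ctrl = len(carrier_ids & set(ctrl["sample_id"]))
    n_case, n_ctrl = len(case), len(ctrl)

    # AR carriers among unrelated patients, split by consanguinity
    unrel_cons = {s for s in unrel if cons.loc[s]}
    unrel_noncons = unrel - unrel_cons
    ar_cons = len(ar_ids & unrel_cons)
    ar_noncons = len(ar_ids & unrel_noncons)

    n_males = len(boys)
    n_females = len(case) - n_males

    summary = {
        "n_cases": n_case,
        "n_controls": n_ctrl,
        "case_male_female_ratio": round_half_up(n_males / n_females, 1)
        if n_females else np.inf,
        "carrier_pct_cases": percent(carriers_cases, n_case, 1),
        "carrier_pct_controls": percent(carriers_ctrl, n_ctrl, 2),
        "carriers_cases": carriers_cases,
        "carriers_controls": carriers_ctrl,
        "n_unrelated_patients": len(unrel),
        "carrier_pct_unrelated_patients": percent(
            len(carrier_ids & unrel), len(unrel), 1),
        "xr_carrier_pct_boys": percent(len(xr_ids & set(boys["sample_id"])),
                                       n_males, 1),
        "ar_carrier_pct_cases": percent(len(ar_ids & case_ids), n_case, 1),
        "ar_carrier_pct_unrelated": percent(len(ar_ids & unrel), len(unrel), 1),
        "n_unrelated_critical": len(unrel_critical),
        "ar_carrier_pct_unrelated_critical": percent(
            len(ar_ids & set(unrel_critical["sample_id"])),
            len(unrel_critical), 1),
        "consanguineous_pct_cases": percent(cons_case, n_case, 1),
        "consanguineous_pct_controls": percent(cons_ctrl, n_ctrl, 1),
        "fisher_consanguinity_by_status_p": fisher_exact_2x2(
            cons_case, n_case - cons_case, cons_ctrl, n_ctrl - cons_ctrl),
        "ar_carrier_pct_unrelated_consanguineous": percent(
            ar_cons, len(unrel_cons), 1),
        "ar_carrier_pct_unrelated_nonconsanguineous": percent(
            ar_noncons, len(unrel_noncons), 1),
        "fisher_ar_by_consanguinity_p": fisher_exact_2x2(
            ar_cons, len(unrel_cons) - ar_cons,
            ar_noncons, len(unrel_noncons) - ar_noncons)
        if unrel_cons and unrel_noncons else np.nan,
    }
    return summary


def summary_frame(summary: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"statistic": list(summary.keys()), "value": list(summary.values())}
    )
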