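"""Firth bias-reduced logistic regression, implemented from its equations.

The penalized log-likelihood is

    l*(b) = l(b) + 1/2 log det( X' W X ),   W = diag(pi (1 - pi)),

whose Jeffreys-prior penalty removes the O(1/n) bias of maximum likelihood
and keeps estimates finite under complete separation.  Newton-Raphson uses
the modified score

    U*_r = sum_i ( y_i - pi_i + h_i (1/2 - pi_i) ) x_ir,

with h_i the diagonal of the penalized-logistic hat matrix
W^1/2 X (X'WX)^-1 X' W^1/2, and step-halving whenever a full step would
decrease l*.  Inference uses the penalized likelihood-ratio statistic
against chi2(1) and profile-penalized-likelihood confidence limits, the
behavior of the standard reference implementation of this estimator.

On a 2x2 design (intercept + binary indicator) the Firth estimate
coincides with adding 0.5 to every cell of the contingency table; tests
exploit that closed form.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .model import FirthFit

_CHI2_95_1DF = chi2.ppf(0.95, 1)


def _check_design(X: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via the null space
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        null = vt[s < s.max() * 1e-10 * max(X.shape)] if len(s) else vt[rank:]
        cols = sorted({int(i) for row in vt[rank:] for i in np.flatnonzero(np.abs(row) > 1e-8)})
        raise ValueError(f"rank-deficient design matrix; collinear columns {cols}")


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """l*(beta): binomial log-likelihood plus half log-det information."""
    eta = X @ beta
    pi = expit(eta)
    # numerically safe log terms via log-sigmoid
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    w = pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _hat_diagonals(X: np.ndarray, w: np.ndarray, info_inv: np.ndarray) -> np.ndarray:
    return w * np.einsum("ij,jk,ik->i", X, info_inv, X)


def _newton(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthFit:
    """Maximize l* over the coordinates in ``free`` (others held fixed)."""
    beta = beta0.astype(float).copy()
    ll = penalized_loglik(X, y, beta)
    converged = False
    it = 0
    max_step = 5.0  # cap on a single Newton move, as in logistf
    for it in range(1, max_iter + 1):
        pi = expit(X @ beta)
        w = pi * (1.0 - pi)
        info = (X * w[:, None]).T @ X
        info_inv = np.linalg.inv(info)
        h = _hat_diagonals(X, w, info_inv)
        score = X.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score[free])) < 1e-8:
            converged = True
            break
        sub = np.ix_(free, free)
        delta = np.zeros_like(beta)
        delta[free] = np.linalg.solve(info[sub], score[free])
        biggest = np.max(np.abs(delta))
        if biggest > max_step:
            delta *= max_step / biggest
        # step-halving: never accept a penalized-likelihood decrease
        step = 1.0
        moved = False
        for _ in range(40):
            cand = beta + step * delta
            ll_new = penalized_loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                moved = True
                break
            step /= 2.0
        if not moved:
            break
        applied = step * delta
        beta, ll = cand, ll_new
        if np.max(np.abs(applied)) < tol:
            converged = True
            break
    pi = expit(X @ beta)
    w = pi * (1.0 - pi)
    info = (X * w[:, None]).T @ X
    h = _hat_diagonals(X, w, np.linalg.inv(info))
    return FirthFit(
        beta=beta,
        hat_diagonals=h,
        penalized_loglik=ll,
        converged=converged,
        n_iterations=it,
        fisher_information=info,
    )


def firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> FirthFit:
    """Fit Firth-penalized logistic regression of binary ``y`` on ``X``.

    ``X`` must include the intercept column.  Estimates are finite even
    under complete separation.  Raises on a rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_design(X)
    free = np.ones(X.shape[1], dtype=bool)
    return _newton(X, y, free, np.zeros(X.shape[1]), max_iter=max_iter, tol=tol)


def _profile_loglik(X: np.ndarray, y: np.ndarray, j: int, value: float,
                    beta_start: np.ndarray) -> float:
    """max over other coefficients of l* with beta_j fixed at ``value``."""
    free = np.ones(X.shape[1], dtype=bool)
    free[j] = False
    beta0 = beta_start.copy()
    beta0[j] = value
    fit = _newton(X, y, free, beta0)
    return fit.penalized_loglik


def firth_inference(
    fit: FirthFit,
    X: np.ndarray,
    y: np.ndarray,
    j: int,
    alpha: float = 0.05,
    coef_tol: float = 1e-6,
) -> tuple[float, float, float, str | None]:
    """Penalized-LRT p-value and profile-likelihood CI for coefficient ``j``.

    Returns (p_value, ci_low, ci_high, warning) on the log-odds scale.
    Falls back to a Wald interval (with a warning) when profiling fails to
    bracket the confidence limit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not fit.converged:
        raise ValueError("inference requires a converged fit")
    ll1 = fit.penalized_loglik
    ll0 = _profile_loglik(X, y, j, 0.0, fit.beta)
    if not np.isfinite(ll0):
        raise ValueError("restricted fit non-convergent")
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(lrt, 1))

    target = ll1 - chi2.ppf(1.0 - alpha, 1) / 2.0
    se = float(np.sqrt(np.linalg.inv(fit.fisher_information)[j, j]))
    warning = None

    def profile(b: float) -> float:
        return _profile_loglik(X, y, j, b, fit.beta)

    limits = []
    for direction in (-1.0, 1.0):
        lo = fit.beta[j]
        hi = None
        step = max(se, 0.5)
        for _ in range(40):
            cand = fit.beta[j] + direction * step
            if profile(cand) < target:
                hi = cand
                break
            lo = cand
            step *= 1.6
        if hi is None:
            warning = "profile_ci_unbracketed_wald_fallback"
            limits.append(fit.beta[j] + direction * 1.959963984540054 * se)
            continue
        # bisection between lo (inside) and hi (outside)
        a, b = lo, hi
        while abs(b - a) > coef_tol:
            mid = 0.5 * (a + b)
            if profile(mid) >= target:
                a = mid
            else:
                b = mid
        limits.append(0.5 * (a + b))
    ci_low, ci_high = sorted(limits)
    return p, float(ci_low), float(ci_high), warning


def firth_2x2(a: float, b: float, c: float, d: float) -> float:
    """Closed-form Firth log-odds-ratio for a 2x2 table: add 0.5 per cell.

    Table layout: exposed cases a, unexposed cases b, exposed controls c,
    unexposed controls d.
    """
    return float(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))
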