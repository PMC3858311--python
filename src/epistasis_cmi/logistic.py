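"""Logistic-regression interaction benchmarks.

Two Wald tests bracket the model-based end of the comparison: a 1 df test on
the single interaction coefficient of a coded model
``status ~ x_G + x_H + x_G * x_H`` (the best case when the coding matches the
generating genetic model), and a joint Wald test on the full interaction
block of the factor-coded saturated model ``status ~ C(G) * C(H)``
((r-1)(c-1) df; "model-free" in the sense of assuming no genotype coding).

Fits are maximum-likelihood logistic regressions on the count-weighted cell
design (statsmodels GLM / IRLS).  Non-convergence and (quasi-)complete
separation are flagged on the result rather than raised: a separated fit has
no finite MLE, so its Wald p-value is reported as NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .tables import CASE, CONTROL, StratifiedGenotypeTable

__all__ = [
    "CODINGS",
    "LogisticFitResult",
    "genotype_scores",
    "logistic_interaction_wald_1df",
    "logistic_interaction_wald_4df",
    "best_coded_1df_p",
]

#: genotype -> score maps for the three classical single-locus models
CODINGS = {
    "additive": {0: 0.0, 1: 1.0, 2: 2.0},
    "dominant": {0: 0.0, 1: 1.0, 2: 1.0},
    "recessive": {0: 0.0, 1: 0.0, 2: 1.0},
}

# |coefficient| beyond this on the logit scale is treated as separation
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class LogisticFitResult:
    method: str
    coefficients: np.ndarray
    covariance: np.ndarray
    wald_statistic: float
    df: int
    p_value: float
    converged: bool
    separation: bool
    notes: str = ""


def genotype_scores(coding, levels) -> np.ndarray:
    """Resolve a coding (name or explicit genotype->score map) on levels."""
    if isinstance(coding, str):
        try:
            coding = CODINGS[coding]
        except KeyError:
            raise ValueError(
                f"unknown coding {coding!r}; choose from {tuple(CODINGS)}"
            ) from None
    return np.array([float(coding[g]) for g in levels])


def _cell_design(table: StratifiedGenotypeTable):
    """Flatten the table to one design row per (stratum, cell) with weights."""
    r, c = table.shape
    gi, hj = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    gi, hj = gi.ravel(), hj.ravel()
    rows_g, rows_h, y, w = [], [], [], []
    for d in (CONTROL, CASE):
        rows_g.append(gi)
        rows_h.append(hj)
        y.append(np.full(gi.size, d, dtype=float))
        w.append(table.counts[d].ravel().astype(float))
    return np.concatenate(rows_g), np.concatenate(rows_h), np.concatenate(y), np.concatenate(w)


def _glm(X, y, w):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        return model.fit(maxiter=100, tol=1e-10)


def _fit(X, y, w, method, df, test_slice, statistic="wald", notes=""):
    keep = w > 0
    Xk, yk, wk = X[keep], y[keep], w[keep]
    try:
        res = _glm(Xk, yk, wk)
        converged = bool(res.converged)
    except Exception as exc:  # perfect separation can abort IRLS outright
        k = X.shape[1]
        return LogisticFitResult(
            method, np.full(k, np.nan), np.full((k, k), np.nan),
            np.nan, df, np.nan, False, True, f"fit failed: {exc}",
        )
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    separation = bool(np.abs(beta).max() > _SEPARATION_BOUND)
    ok = converged and not separation
    if ok:
        if statistic == "wald":
            b = beta[test_slice]
            V = cov[test_slice, test_slice]
            try:
                stat = float(b @ np.linalg.solve(V, b))
                p = float(chi2.sf(stat, df))
            except np.linalg.LinAlgError:
                ok, stat, p = False, np.nan, np.nan
                notes = (notes + "; " if notes else "") + "singular Wald covariance"
        elif statistic == "lr":
            null_cols = np.ones(X.shape[1], dtype=bool)
            null_cols[test_slice] = False
            try:
                res0 = _glm(Xk[:, null_cols], yk, wk)
                stat = float(max(2.0 * (res.llf - res0.llf), 0.0))
                p = float(chi2.sf(stat, df))
            except Exception:
                ok, stat, p = False, np.nan, np.nan
                notes = (notes + "; " if notes else "") + "null-model fit failed"
        else:
            raise ValueError(f"unknown statistic {statistic!r}; use 'wald' or 'lr'")
    if not ok:
        stat, p = np.nan, np.nan
        if not converged:
            notes = (notes + "; " if notes else "") + "IRLS did not converge"
        if separation:
            notes = (notes + "; " if notes else "") + "separation suspected"
    return LogisticFitResult(method, beta, cov, stat, df, p, converged, separation, notes)


def logistic_interaction_wald_1df(
    table: StratifiedGenotypeTable, coding_g="additive", coding_h="additive",
    statistic: str = "wald",
) -> LogisticFitResult:
    """1 df test on the interaction coefficient of the coded model.

    ``statistic='wald'`` (default) is the squared z of the interaction
    coefficient; ``'lr'`` is the likelihood-ratio test against the nested
    main-effects model.
    """
    sg = genotype_scores(coding_g, table.levels_g)
    sh = genotype_scores(coding_h, table.levels_h)
    gi, hj, y, w = _cell_design(table)
    xg, xh = sg[gi], sh[hj]
    X = np.column_stack([np.ones_like(xg), xg, xh, xg * xh])
    return _fit(X, y, w, "logit_1df", 1, slice(3, 4), statistic)


def logistic_interaction_wald_4df(
    table: StratifiedGenotypeTable, statistic: str = "wald"
) -> LogisticFitResult:
    """Joint test on all interaction terms of the factor-coded model.

    df = (r-1)(c-1): 4 for two fully observed triallelic-genotype loci,
    fewer when a genotype class is structurally absent.  ``statistic='wald'``
    tests the interaction block against its estimated covariance; ``'lr'``
    compares the saturated fit to the main-effects-only fit.
    """
    r, c = table.shape
    gi, hj, y, w = _cell_design(table)
    cols = [np.ones_like(y)]
    for a in range(1, r):
        cols.append((gi == a).astype(float))
    for b in range(1, c):
        cols.append((hj == b).astype(float))
    for a in range(1, r):
        for b in range(1, c):
            cols.append(((gi == a) & (hj == b)).astype(float))
    X = np.column_stack(cols)
    df = (r - 1) * (c - 1)
    return _fit(X, y, w, "logit_4df", df, slice(1 + (r - 1) + (c - 1), X.shape[1]), statistic)


def best_coded_1df_p(table: StratifiedGenotypeTable):
    """Smallest 1 df interaction p-value across the additive x additive,
    dominant x dominant and recessive x recessive codings.

    This mirrors the "lowest p among logistic models" summary sometimes
    reported alongside these tables; it is NOT corrected for trying three
    models.  Returns ``(p, coding_name, result)``; separated or
    non-converged codings are skipped.
    """
    best = (np.inf, None, None)
    for name in ("additive", "dominant", "recessive"):
        res = logistic_interaction_wald_1df(table, name, name)
        if np.isfinite(res.p_value) and res.p_value < best[0]:
            best = (res.p_value, name, res)
    return best
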