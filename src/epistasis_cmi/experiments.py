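"""Monte-Carlo harness: type-I error tables, power curves, Q-Q diagnostics.

Each replicate draws one case-control table from a scenario and applies a
set of metrics; rejection rates at a nominal level are reported with
binomial standard errors.  Per-replicate seeds are spawned from the master
seed by a counter-based stream (SeedSequence(master, replicate)), so every
metric sees the identical sequence of tables and adding a metric never
perturbs the data.

Replicates on which a fit fails (logistic separation / non-convergence) are
excluded from that metric's denominator and counted separately — they are
never silently treated as rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2

from .logistic import logistic_interaction_wald_1df, logistic_interaction_wald_4df
from .metrics import gamete_cmi_test, geno_cmi_test, geno_mi_test
from .simulate import ScenarioConfig, conditional_genotype_distributions, sample_case_control

__all__ = [
    "ALL_METRICS",
    "RejectionRateResult",
    "QQData",
    "run_rejection_rate",
    "run_power_curve",
    "qq_statistics",
]

#: metric name -> (callable table -> (p_value, ok), reference df callable)
ALL_METRICS = ("geno_mi", "geno_cmi", "gamete_cmi", "logit_1df", "logit_4df")


@dataclass(frozen=True)
class RejectionRateResult:
    """Monte-Carlo rejection proportion for one metric in one scenario."""

    metric: str
    scenario: str
    alpha: float
    rejection_rate: float
    standard_error: float
    n_replicates: int  # evaluable replicates (denominator)
    n_failed: int
    seed: int

    def __str__(self):
        return (
            f"{self.scenario} {self.metric}: {self.rejection_rate:.3f} "
            f"(SE {self.standard_error:.3f}, n={self.n_replicates}, "
            f"failed={self.n_failed})"
        )


@dataclass(frozen=True)
class QQData:
    """Sorted observed statistics with matched theoretical quantiles."""

    observed: np.ndarray
    theoretical: np.ndarray
    metric: str
    df: int


def _apply_metric(table, metric, config):
    """Return (statistic, df, p_value, ok) for one metric on one table."""
    if metric == "geno_mi":
        r = geno_mi_test(table)
    elif metric == "geno_cmi":
        r = geno_cmi_test(table)
    elif metric == "gamete_cmi":
        r = gamete_cmi_test(table)
    elif metric == "logit_1df":
        res = logistic_interaction_wald_1df(table, config.model, config.model)
        return res.wald_statistic, res.df, res.p_value, np.isfinite(res.p_value)
    elif metric == "logit_4df":
        res = logistic_interaction_wald_4df(table)
        return res.wald_statistic, res.df, res.p_value, np.isfinite(res.p_value)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {ALL_METRICS}")
    return r.statistic, r.df, r.p_value, True


def _replicate_tables(config: ScenarioConfig):
    """Yield the seeded sequence of replicate tables for a scenario."""
    pop = config.population()
    pen = config.penetrance()
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, rep)))
        yield sample_case_control(pop, pen, config.n_case, config.n_control, rng)


def run_rejection_rate(config: ScenarioConfig, metrics=("geno_cmi",)) -> dict:
    """Estimate per-metric rejection proportions at ``config.alpha``.

    Returns ``{metric: RejectionRateResult}``; fully reproducible from
    ``config.seed``.
    """
    metrics = tuple(metrics)
    hits = {m: 0 for m in metrics}
    fails = {m: 0 for m in metrics}
    for table in _replicate_tables(config):
        for m in metrics:
            _, _, p, ok = _apply_metric(table, m, config)
            if not ok:
                fails[m] += 1
            elif p < config.alpha:
                hits[m] += 1
    out = {}
    for m in metrics:
        n_eval = config.n_replicates - fails[m]
        rate = hits[m] / n_eval if n_eval else float("nan")
        se = float(np.sqrt(rate * (1 - rate) / n_eval)) if n_eval else float("nan")
        out[m] = RejectionRateResult(
            m, config.label or "scenario", config.alpha, rate, se,
            n_eval, fails[m], config.seed,
        )
    return out


def run_power_curve(config: ScenarioConfig, or_gh_grid, metrics=("geno_cmi",)) -> list:
    """Rejection rates along a grid of interaction odds ratios.

    Each grid point reuses the scenario with ``or_gh`` replaced (seed offset
    by the grid index so points are independent).  Returns a list of
    ``(or_gh, {metric: RejectionRateResult})`` pairs.
    """
    results = []
    for i, og in enumerate(or_gh_grid):
        if og < 1.0:
            raise ValueError("or_gh grid values must be >= 1")
        cfg = replace(
            config, or_gh=float(og), seed=int(config.seed) + 100_000 * (i + 1),
            label=(config.label or "power") + f":or_gh={og:g}",
        )
        results.append((float(og), run_rejection_rate(cfg, metrics)))
    return results


def qq_statistics(config: ScenarioConfig, metric: str = "geno_cmi") -> QQData:
    """Observed statistics sorted against chi-squared plotting positions.

    Theoretical quantiles use positions (i - 0.5) / n for i = 1..n on the
    chi-squared law with the metric's reference df.
    """
    stats, dfs = [], []
    for table in _replicate_tables(config):
        s, df, _, ok = _apply_metric(table, metric, config)
        if ok:
            stats.append(s)
            dfs.append(df)
    observed = np.sort(np.asarray(stats))
    df = int(dfs[0]) if dfs else 0
    n = observed.size
    theo = chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df) if n else np.array([])
    return QQData(observed, theo, metric, df)
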