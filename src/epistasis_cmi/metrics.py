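"""Entropy-based interaction tests for two-locus case-control tables.

Three metrics, all in nats:

* **GenoMI** — mutual information between the flattened joint genotype
  S = (G, H) and disease status D.  It responds to *any* difference in joint
  genotype distribution between cases and controls, so marginal (main)
  effects inflate it even without interaction.
* **GenoCMI** — conditional mutual information I(G; H | D): the
  case-fraction-weighted within-stratum MI between the two loci.  Under a
  multiplicative (no-interaction) risk model for a rare disease this is
  asymptotically zero, which is what makes it a pure interaction test.
* **GameteCMI** — the allelic analogue: within each stratum the four gamete
  frequencies are estimated by EM and the 2x2 allelic MI is computed; the
  stratum-weighted sum measures conditional allelic dependence.

Each metric is calibrated as ``statistic = 2 * N * metric`` (N individuals)
against an upper-tail chi-squared reference.  For GenoMI the reference uses
the full-table degrees of freedom (8 for two triallelic-genotype loci)
regardless of empty genotype classes, matching how the statistic behaves in
published worked examples; for GenoCMI the degrees of freedom follow the
structural table dimension, 2*(r-1)*(c-1); GameteCMI has 2 df (one per
stratum).  Both df conventions are exposed through ``df_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .em import em_gamete_frequencies
from .tables import CASE, CONTROL, StratifiedGenotypeTable

__all__ = [
    "TestResult",
    "plugin_mi",
    "chi2_upper_tail",
    "geno_mi_test",
    "geno_cmi_test",
    "gamete_cmi_test",
    "run_test",
    "METRIC_NAMES",
]

METRIC_NAMES = ("geno_mi", "geno_cmi", "gamete_cmi")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one interaction test on one table."""

    method: str
    metric_value: float  # mutual-information value, nats
    statistic: float  # scaled chi-squared statistic
    df: int
    p_value: float
    n_individuals: int
    notes: str = ""

    def __str__(self):
        return (
            f"{self.method}: metric={self.metric_value:.6g} nats, "
            f"stat={self.statistic:.4f}, df={self.df}, p={self.p_value:.3E}"
        )


def plugin_mi(joint_probs) -> float:
    """Plug-in mutual information (nats) of a joint probability matrix.

    ``0 * log 0`` terms contribute zero; the result is clipped at 0 to guard
    against floating-point round-off on (near-)independent inputs.
    """
    p = np.asarray(joint_probs, dtype=float)
    if (p < 0).any():
        raise ValueError("joint_probs: negative entry")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"joint_probs must sum to 1 (got {total!r})")
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    mask = p > 0
    terms = np.zeros_like(p)
    terms[mask] = p[mask] * np.log(p[mask] / (pr @ pc)[mask])
    return float(max(terms.sum(), 0.0))


def chi2_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail chi-squared probability P(X >= statistic), X ~ chi2(df)."""
    if statistic < 0:
        raise ValueError("statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(chi2.sf(statistic, df))


def _full_dim(levels) -> int:
    """Structural genotype dimension of a diallelic locus (always 3)."""
    return 3


def geno_mi_test(table: StratifiedGenotypeTable, df_mode: str = "fixed") -> TestResult:
    """Mutual information between the joint genotype and disease status.

    ``df_mode='fixed'`` (default) uses the full two-locus genotype grid,
    df = 3*3 - 1 = 8; ``'structural'`` uses the observed joint-category
    count minus one.
    """
    N = table.n
    joint = np.stack(
        [table.control_counts.ravel(), table.case_counts.ravel()], axis=1
    ).astype(float)
    mi = plugin_mi(joint / N)
    stat = 2.0 * N * mi
    if df_mode == "fixed":
        df = _full_dim(table.levels_g) * _full_dim(table.levels_h) - 1
    elif df_mode == "structural":
        df = table.shape[0] * table.shape[1] - 1
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    return TestResult("geno_mi", mi, stat, df, chi2_upper_tail(stat, df), N)


def geno_cmi_test(table: StratifiedGenotypeTable, df_mode: str = "structural") -> TestResult:
    """Conditional mutual information I(G; H | D) on genotype classes.

    metric = sum_d (N_d / N) * MI_d, statistic = 2 * N * metric; with
    ``df_mode='structural'`` (default) df = 2*(r-1)*(c-1) for an r x c
    genotype grid, with ``'fixed'`` df = 8.
    """
    N = table.n
    notes = []
    metric = 0.0
    for d, name in ((CONTROL, "control"), (CASE, "case")):
        cnt = table.counts[d].astype(float)
        nd = cnt.sum()
        if (cnt.sum(axis=1) > 0).sum() < 2 or (cnt.sum(axis=0) > 0).sum() < 2:
            notes.append(f"degenerate stratum '{name}': fewer than 2 non-empty rows/columns")
            continue
        metric += (nd / N) * plugin_mi(cnt / nd)
    stat = 2.0 * N * metric
    r, c = table.shape
    if df_mode == "structural":
        df = 2 * (r - 1) * (c - 1)
    elif df_mode == "fixed":
        df = 8
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    return TestResult(
        "geno_cmi", metric, stat, df, chi2_upper_tail(stat, df), N, "; ".join(notes)
    )


def gamete_cmi_test(
    table: StratifiedGenotypeTable,
    scale: str = "individuals",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> TestResult:
    """Conditional allelic mutual information on EM-estimated gametes.

    Within each stratum the four gamete frequencies are estimated by EM and
    the 2x2 allelic MI computed; metric = sum_d (N_d / N) * MI_d.  With
    ``scale='individuals'`` (default) the statistic is ``2 * N * metric``
    with N the number of individuals — the convention whose null
    distribution matches chi-squared(2) for unphased data;
    ``scale='gametes'`` uses the 2N gamete count instead (statistic
    ``4 * N * metric``), the per-stratum allelic G-test sum, which is
    anti-conservative when phase has to be inferred.
    """
    N = table.n
    notes = []
    metric = 0.0
    for d, name in ((CONTROL, "control"), (CASE, "case")):
        cnt = table.counts[d].astype(float)
        nd = cnt.sum()
        freqs = em_gamete_frequencies(
            cnt, table.levels_g, table.levels_h, tol=tol, max_iter=max_iter
        )
        if freqs.notes:
            notes.append(f"{name}: {freqs.notes}")
        if not freqs.converged:
            continue
        if freqs.allele_freq_g in (0.0, 1.0) or freqs.allele_freq_h in (0.0, 1.0):
            notes.append(f"monomorphic locus in stratum '{name}'; contribution 0")
            continue
        metric += (nd / N) * plugin_mi(freqs.h)
    if scale == "individuals":
        stat = 2.0 * N * metric
    elif scale == "gametes":
        stat = 4.0 * N * metric
    else:
        raise ValueError(f"unknown scale {scale!r}")
    df = 2
    return TestResult(
        "gamete_cmi", metric, stat, df, chi2_upper_tail(stat, df), N, "; ".join(notes)
    )


def run_test(table: StratifiedGenotypeTable, method: str, **kwargs) -> TestResult:
    """Dispatch by metric name ('geno_mi', 'geno_cmi', 'gamete_cmi')."""
    try:
        fn = {"geno_mi": geno_mi_test, "geno_cmi": geno_cmi_test,
              "gamete_cmi": gamete_cmi_test}[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {METRIC_NAMES}") from None
    return fn(table, **kwargs)
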