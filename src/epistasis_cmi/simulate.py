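"""Retrospective case-control simulator for two unlinked diallelic loci.

The population model is Hardy-Weinberg equilibrium at each locus and linkage
equilibrium between the loci, so the 3x3 joint genotype probabilities are
the outer product of two binomial(2, p) marginals.  Disease risk follows a
logistic penetrance model

    logit f_ij = beta0 + ln(OR_G) x_i + ln(OR_H) x_j + ln(OR_GH) x_i x_j

where x are genotype scores under an additive (0,1,2), dominant (0,1,1) or
recessive (0,0,1) coding, the ORs are exact odds ratios per score unit, and
the intercept beta0 is solved so the population prevalence
sum_ij P_ij f_ij equals a target K.  Case-control samples are drawn directly
from the retrospective conditional cell distributions
P(cell | case) = P_ij f_ij / K and P(cell | control) = P_ij (1 - f_ij) / (1 - K),
which is the sampling law a case-control design induces on an infinite
population; the draw is a pair of multinomials, exactly reproducible from an
integer seed.

``schema_config`` encodes the nine study designs used throughout the
simulation experiments: a common (K = 0.02) or rare (K = 0.0001) disease,
main effects at zero, one or both loci, 1:1 or 1:2 case/control ratios, and
two power designs with a genuine interaction effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .logistic import CODINGS, genotype_scores
from .tables import StratifiedGenotypeTable, table_from_counts

__all__ = [
    "PopulationModel",
    "PenetranceTable",
    "ScenarioConfig",
    "population_genotype_frequencies",
    "build_penetrance",
    "conditional_genotype_distributions",
    "sample_case_control",
    "sample_scenario",
    "schema_config",
    "SCHEMA_NUMBERS",
]

DEFAULT_P_G = 0.30
DEFAULT_P_H = 0.42
SCHEMA_NUMBERS = tuple(range(1, 10))


def _hwe(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


@dataclass(frozen=True)
class PopulationModel:
    """HWE x linkage-equilibrium genotype law for the two loci."""

    p_g: float
    p_h: float
    joint: np.ndarray  # 3x3, rows G, cols H

    @property
    def marginal_g(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_h(self) -> np.ndarray:
        return self.joint.sum(axis=0)


@dataclass(frozen=True)
class PenetranceTable:
    """3x3 penetrances under the logistic two-locus model."""

    f: np.ndarray
    coding_g: str
    coding_h: str
    or_g: float
    or_h: float
    or_gh: float
    beta0: float
    prevalence_target: float
    achieved_prevalence: float

    def marginal_penetrance_g(self, pop: PopulationModel) -> np.ndarray:
        """f_i. = sum_j P(j) f_ij (marginalised over the independent locus)."""
        return self.f @ pop.marginal_h

    def marginal_penetrance_h(self, pop: PopulationModel) -> np.ndarray:
        return self.f.T @ pop.marginal_g


def population_genotype_frequencies(p_g: float = DEFAULT_P_G, p_h: float = DEFAULT_P_H) -> PopulationModel:
    """Joint genotype probabilities under HWE and linkage equilibrium."""
    for name, p in (("p_g", p_g), ("p_h", p_h)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")
    joint = np.outer(_hwe(p_g), _hwe(p_h))
    joint.setflags(write=False)
    return PopulationModel(p_g, p_h, joint)


def _penetrance_matrix(beta0, xg, xh, lg, lh, lgh):
    eta = beta0 + lg * xg[:, None] + lh * xh[None, :] + lgh * xg[:, None] * xh[None, :]
    return 1.0 / (1.0 + np.exp(-eta))


def build_penetrance(
    pop: PopulationModel,
    coding_g: str = "additive",
    coding_h: str = "additive",
    or_g: float = 1.0,
    or_h: float = 1.0,
    or_gh: float = 1.0,
    prevalence: float = 0.02,
) -> PenetranceTable:
    """Solve the intercept so the model attains a target prevalence K.

    The map beta0 -> sum_ij P_ij f_ij is strictly increasing with range
    (0, 1), so a bracketing root search on [-50, 50] pins beta0; the
    achieved prevalence is recorded and agrees with K to ~1e-10.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie strictly in (0, 1)")
    for name, v in (("or_g", or_g), ("or_h", or_h), ("or_gh", or_gh)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    xg = genotype_scores(coding_g, (0, 1, 2))
    xh = genotype_scores(coding_h, (0, 1, 2))
    lg, lh, lgh = np.log(or_g), np.log(or_h), np.log(or_gh)

    def gap(b0):
        return float((pop.joint * _penetrance_matrix(b0, xg, xh, lg, lh, lgh)).sum() - prevalence)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("target prevalence unattainable within the intercept bracket")
    beta0 = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    f = _penetrance_matrix(beta0, xg, xh, lg, lh, lgh)
    f.setflags(write=False)
    achieved = float((pop.joint * f).sum())
    cg = coding_g if isinstance(coding_g, str) else "custom"
    ch = coding_h if isinstance(coding_h, str) else "custom"
    return PenetranceTable(f, cg, ch, or_g, or_h, or_gh, float(beta0), prevalence, achieved)


def conditional_genotype_distributions(pop: PopulationModel, pen: PenetranceTable):
    """Retrospective cell laws: (P(cell | case), P(cell | control))."""
    num_case = pop.joint * pen.f
    num_ctrl = pop.joint * (1.0 - pen.f)
    return num_case / num_case.sum(), num_ctrl / num_ctrl.sum()


def sample_case_control(
    pop: PopulationModel,
    pen: PenetranceTable,
    n_case: int,
    n_control: int,
    seed,
) -> StratifiedGenotypeTable:
    """Draw a case-control genotype table (multinomial per stratum).

    ``seed`` may be an integer, a SeedSequence or a Generator; integer seeds
    give bit-identical tables on repeat.  Zero cells are retained and the
    table keeps the full {0,1,2} x {0,1,2} grid.
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("n_case and n_control must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_case, p_ctrl = conditional_genotype_distributions(pop, pen)
    case = rng.multinomial(n_case, p_case.ravel()).reshape(3, 3)
    ctrl = rng.multinomial(n_control, p_ctrl.ravel()).reshape(3, 3)
    return table_from_counts(case, ctrl, (0, 1, 2), (0, 1, 2))


# ---------------------------------------------------------------------------
# scenario configuration and schema presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified simulation scenario."""

    p_g: float = DEFAULT_P_G
    p_h: float = DEFAULT_P_H
    prevalence: float = 0.02
    model: str = "additive"  # coding used at both loci and for the interaction
    or_g: float = 1.0
    or_h: float = 1.0
    or_gh: float = 1.0
    n_case: int = 1000
    n_control: int = 1000
    n_replicates: int = 1000
    alpha: float = 0.01
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.model not in CODINGS:
            raise ValueError(f"unknown model {self.model!r}; choose from {tuple(CODINGS)}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if min(self.or_g, self.or_h, self.or_gh) <= 0:
            raise ValueError("odds ratios must be positive")
        if self.n_case < 1 or self.n_control < 1 or self.n_replicates < 1:
            raise ValueError("n_case, n_control, n_replicates must be >= 1")

    def population(self) -> PopulationModel:
        return population_genotype_frequencies(self.p_g, self.p_h)

    def penetrance(self) -> PenetranceTable:
        return build_penetrance(
            self.population(), self.model, self.model,
            self.or_g, self.or_h, self.or_gh, self.prevalence,
        )


def sample_scenario(config: ScenarioConfig, seed=None) -> StratifiedGenotypeTable:
    """Draw one table under a scenario (seed defaults to ``config.seed``)."""
    return sample_case_control(
        config.population(), config.penetrance(), config.n_case, config.n_control,
        config.seed if seed is None else seed,
    )


def schema_config(
    schema: int,
    model: str = "additive",
    or_main: float = 2.0,
    or_gh: float = 1.0,
    n_replicates: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> ScenarioConfig:
    """Preset for one of the nine study designs.

    1: global null, K=0.02.                 2: main effect at G only.
    3: main effects at both loci.           4: like 2, rare disease K=1e-4.
    5: like 3, rare disease.                6: like 2, 1:2 case/control.
    7: like 3, 1:2 case/control.            8: interaction only (or_gh).
    9: interaction plus main effect at G (OR_G = 2.0).

    ``or_main`` sets the main-effect odds ratio where one is present
    (the designs were run at 2.0 and 3.0); ``or_gh`` sets the interaction
    odds ratio for schemas 8 and 9.
    """
    if schema not in SCHEMA_NUMBERS:
        raise ValueError(f"schema must be in {SCHEMA_NUMBERS}")
    cfg = dict(
        model=model, n_replicates=n_replicates, alpha=alpha, seed=seed,
        label=f"schema{schema}:{model}",
    )
    if schema == 1:
        pass
    elif schema in (2, 4, 6):
        cfg.update(or_g=or_main)
    elif schema in (3, 5, 7):
        cfg.update(or_g=or_main, or_h=or_main)
    elif schema == 8:
        cfg.update(or_gh=or_gh)
    elif schema == 9:
        cfg.update(or_g=2.0, or_gh=or_gh)
    if schema in (4, 5):
        cfg.update(prevalence=1e-4)
    if schema in (6, 7):
        cfg.update(n_control=2000)
    return ScenarioConfig(**cfg)
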