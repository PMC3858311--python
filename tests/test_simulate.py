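"""Two-locus simulator: population law, penetrance solve, sampling."""

import numpy as np
import pytest

from epistasis_cmi import (
    ScenarioConfig,
    build_penetrance,
    conditional_genotype_distributions,
    population_genotype_frequencies,
    sample_case_control,
    schema_config,
)
from epistasis_cmi.logistic import genotype_scores


class TestPopulation:
    def test_hwe_closed_form(self):
        pop = population_genotype_frequencies(0.30, 0.42)
        assert pop.marginal_g == pytest.approx([0.49, 0.42, 0.09])

    def test_double_het_probability(self):
        pop = population_genotype_frequencies(0.5, 0.5)
        assert pop.joint[1, 1] == pytest.approx(0.25)

    def test_outer_product_of_marginals(self, rng):
        for _ in range(5):
            p, q = rng.uniform(0.05, 0.95, 2)
            pop = population_genotype_frequencies(p, q)
            assert np.allclose(
                pop.joint, np.outer(pop.marginal_g, pop.marginal_h), atol=0
            )
            assert pop.joint.sum() == pytest.approx(1.0)

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValueError):
            population_genotype_frequencies(0.0, 0.5)
        with pytest.raises(ValueError):
            population_genotype_frequencies(0.5, 1.0)


class TestPenetrance:
    def test_flat_model(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, prevalence=0.02)
        assert np.allclose(pen.f, 0.02, atol=1e-10)

    def test_logistic_odds_identity(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(
            pop, "dominant", "dominant", or_g=2, or_h=2, or_gh=3, prevalence=0.02
        )
        odds = pen.f / (1 - pen.f)
        assert odds[2, 2] / odds[0, 0] == pytest.approx(12.0, rel=1e-9)

    def test_logit_linearity_in_scores(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(
            pop, "additive", "additive", or_g=1.7, or_h=1.3, or_gh=1.4, prevalence=0.05
        )
        xg = genotype_scores("additive", (0, 1, 2))
        logit = np.log(pen.f / (1 - pen.f))
        expect = (
            pen.beta0
            + np.log(1.7) * xg[:, None]
            + np.log(1.3) * xg[None, :]
            + np.log(1.4) * xg[:, None] * xg[None, :]
        )
        assert np.allclose(logit, expect, atol=1e-10)

    def test_beta0_against_independent_bisection(self):
        pop = population_genotype_frequencies(0.30, 0.42)
        pen = build_penetrance(pop, "additive", "additive", or_g=2.0, prevalence=0.02)
        xg = genotype_scores("additive", (0, 1, 2))

        def prevalence_at(b0):
            eta = b0 + np.log(2.0) * xg[:, None] + 0.0 * xg[None, :]
            return (pop.joint / (1 + np.exp(-eta))).sum()

        lo, hi = -50.0, 50.0
        for _ in range(200):  # plain bisection oracle
            mid = (lo + hi) / 2
            if prevalence_at(mid) < 0.02:
                lo = mid
            else:
                hi = mid
        assert pen.beta0 == pytest.approx((lo + hi) / 2, abs=1e-8)
        assert pen.achieved_prevalence == pytest.approx(0.02, abs=1e-8)

    @pytest.mark.parametrize("coding", ["additive", "dominant", "recessive"])
    @pytest.mark.parametrize("k", [0.0001, 0.02, 0.2])
    @pytest.mark.parametrize("ors", [(1, 1, 1), (2, 1, 1), (3, 3, 1), (2, 1, 2.5)])
    def test_prevalence_recovery(self, coding, k, ors):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, coding, coding, *ors, prevalence=k)
        assert pen.achieved_prevalence == pytest.approx(k, abs=1e-8)

    def test_marginal_penetrance_reduction(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, "dominant", "dominant", or_g=2, prevalence=0.02)
        fg = pen.marginal_penetrance_g(pop)
        assert (pop.marginal_g * fg).sum() == pytest.approx(0.02, abs=1e-10)

    def test_invalid_inputs(self):
        pop = population_genotype_frequencies()
        with pytest.raises(ValueError):
            build_penetrance(pop, or_g=-1.0)
        with pytest.raises(ValueError):
            build_penetrance(pop, prevalence=1.5)


class TestConditionalDistributions:
    def test_flat_model_matches_population(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, prevalence=0.02)
        p_case, p_ctrl = conditional_genotype_distributions(pop, pen)
        assert np.allclose(p_case, pop.joint, atol=1e-12)
        assert np.allclose(p_ctrl, pop.joint, atol=1e-12)

    def test_law_of_total_probability(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, "dominant", "dominant", 2, 1, 3, prevalence=0.02)
        k = pen.achieved_prevalence
        p_case, p_ctrl = conditional_genotype_distributions(pop, pen)
        assert np.allclose(k * p_case + (1 - k) * p_ctrl, pop.joint, atol=1e-12)

    def test_enumeration_oracle(self):
        """Cell-by-cell Bayes computation for a recessive main-effect model."""
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, "recessive", "recessive", or_g=3.0, prevalence=0.02)
        p_case, p_ctrl = conditional_genotype_distributions(pop, pen)
        num_case = np.empty((3, 3))
        num_ctrl = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                num_case[i, j] = pop.joint[i, j] * pen.f[i, j]
                num_ctrl[i, j] = pop.joint[i, j] * (1 - pen.f[i, j])
        assert np.abs(p_case - num_case / num_case.sum()).max() < 1e-12
        assert np.abs(p_ctrl - num_ctrl / num_ctrl.sum()).max() < 1e-12
        assert p_case.sum() == pytest.approx(1.0) and p_ctrl.sum() == pytest.approx(1.0)


class TestSampling:
    def test_seeded_determinism(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, "additive", "additive", or_g=2, prevalence=0.02)
        a = sample_case_control(pop, pen, 500, 500, seed=42)
        b = sample_case_control(pop, pen, 500, 500, seed=42)
        assert np.array_equal(a.counts, b.counts)
        c = sample_case_control(pop, pen, 500, 500, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_null_model_concentration(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, prevalence=0.02)
        n = 10**6
        t = sample_case_control(pop, pen, n, 1, seed=7)
        freq = t.case_counts / n
        se = np.sqrt(pop.joint * (1 - pop.joint) / n)
        assert np.all(np.abs(freq - pop.joint) <= 4 * se + 1e-12)

    def test_main_effect_shifts_case_allele_frequency(self):
        pop = population_genotype_frequencies()
        pen = build_penetrance(pop, "additive", "additive", or_g=2.0, prevalence=0.02)
        p_case, p_ctrl = conditional_genotype_distributions(pop, pen)
        counts = np.arange(3)
        analytic_case = (p_case.sum(1) * counts).sum() / 2
        analytic_ctrl = (p_ctrl.sum(1) * counts).sum() / 2
        n = 10**5
        t = sample_case_control(pop, pen, n, n, seed=11)
        emp_case = (t.case_counts.sum(1) * counts).sum() / (2 * n)
        emp_ctrl = (t.control_counts.sum(1) * counts).sum() / (2 * n)
        se = np.sqrt(analytic_case * (1 - analytic_case) / (2 * n))
        assert emp_case > emp_ctrl
        assert abs(emp_case - analytic_case) < 4 * se
        assert abs(emp_ctrl - analytic_ctrl) < 4 * se


class TestScenarioConfig:
    def test_schema_presets(self):
        assert schema_config(1).or_g == 1.0 and schema_config(1).prevalence == 0.02
        assert schema_config(2, or_main=3.0).or_g == 3.0
        assert schema_config(3, or_main=2.0).or_h == 2.0
        assert schema_config(4).prevalence == pytest.approx(1e-4)
        assert schema_config(6).n_control == 2000 and schema_config(6).n_case == 1000
        s9 = schema_config(9, or_gh=2.0)
        assert s9.or_g == 2.0 and s9.or_gh == 2.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(model="codominant")
        with pytest.raises(ValueError):
            ScenarioConfig(alpha=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig(or_g=0.0)
        with pytest.raises(ValueError):
            schema_config(10)
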