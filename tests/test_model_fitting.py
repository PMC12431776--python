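"""Least squares on exponent-set designs: exactness, oracles, diagnostics."""

import numpy as np
import pytest

import genprice as gp
from genprice.model_fitting import design_matrix
from conftest import GRID_LEVELS, random_transition, spec_menu


class TestDesignMatrix:
    def test_constant_and_identity_columns(self):
        pop = gp.ParentPopulation(p=np.array([0.0, 1.0]))
        X = design_matrix(pop, gp.model_a())
        assert np.array_equal(X, [[1.0, 0.0], [1.0, 1.0]])

    def test_zero_to_the_zero_is_one(self):
        pop = gp.ParentPopulation(p=np.array([0.0]))
        X = design_matrix(pop, gp.model_a())
        assert X[0, 0] == 1.0

    def test_interaction_model_row(self):
        pop = gp.ParentPopulation(p=np.array([1.0]), q=np.array([1.0]))
        X = design_matrix(pop, gp.model_3())
        assert np.array_equal(X[0], [1.0, 1.0, 1.0, 1.0])

    def test_column_order_is_sorted_terms(self):
        spec = gp.ModelSpec.from_string("1,p*q,q,p")
        assert spec.terms == ((0, 0), (0, 1), (1, 0), (1, 1))


class TestFitExactness:
    def test_noiseless_linear_interpolation(self, grid11):
        t = gp.Transition(
            parents=grid11, offspring_counts=1.0 + grid11.p, expected_mode=True
        )
        fit = gp.fit_least_squares(t, gp.model_a())
        assert fit.beta_hat[(0, 0)] == pytest.approx(1.0, abs=1e-12)
        assert fit.beta_hat[(1, 0)] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(fit.residuals) < 1e-12)
        assert fit.exact_fit

    def test_underspecified_slope_closed_form(self, grid11):
        """Linear fit to noiseless quadratic truth: β̂₁ = β₁ + β₂·Cov(p,p²)/Var(p)."""
        t = gp.Transition(
            parents=grid11, offspring_counts=1.0 + grid11.p**2, expected_mode=True
        )
        fit = gp.fit_least_squares(t, gp.model_a())
        ratio = gp.cov(grid11.p, grid11.p**2) / gp.var(grid11.p)
        assert ratio == pytest.approx(1.0, abs=1e-12)
        assert fit.beta_hat[(1, 0)] == pytest.approx(0.0 + 1.0 * ratio, abs=1e-9)

    def test_residuals_orthogonal_to_all_regressors(self):
        rng = np.random.default_rng(17)
        t = random_transition(rng, n=50, social=True)
        for spec in spec_menu(social=True):
            fit = gp.fit_least_squares(t, spec)
            X = design_matrix(t.parents, spec)
            assert np.max(np.abs(X.T @ fit.residuals)) < 1e-8
            assert abs(np.mean(fit.residuals)) < 1e-10


class TestFitAgainstOracles:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_normal_equations_oracle(self, seed):
        """Small-n cross-check: solve X'Xβ = X'w directly."""
        rng = np.random.default_rng(seed)
        t = random_transition(rng, n=int(rng.integers(10, 51)), social=True)
        for spec in spec_menu(social=True):
            fit = gp.fit_least_squares(t, spec)
            X = design_matrix(t.parents, spec)
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ t.fitness)
            got = np.array([fit.beta_hat[term] for term in spec.terms])
            np.testing.assert_allclose(got, beta_oracle, atol=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        t = random_transition(rng, n=80, social=True)
        spec = gp.model_3()
        fit = gp.fit_least_squares(t, spec)
        X = design_matrix(t.parents, spec)
        res = sm.OLS(t.fitness, X).fit()
        np.testing.assert_allclose(
            [fit.beta_hat[term] for term in spec.terms], res.params, atol=1e-10
        )
        np.testing.assert_allclose(
            [fit.standard_errors[term] for term in spec.terms], res.bse, atol=1e-10
        )


class TestRankDeficiency:
    def test_binary_p_makes_quadratic_collinear(self):
        rng = np.random.default_rng(1)
        p = rng.integers(0, 2, 30).astype(float)
        t = gp.Transition(
            parents=gp.ParentPopulation(p=p),
            offspring_counts=rng.poisson(2, 30).astype(float),
        )
        with pytest.raises(gp.IdentifiabilityError, match=r"\(1, 0\)|\(2, 0\)"):
            gp.fit_least_squares(t, gp.model_b())

    def test_clonal_pairing_makes_q_collinear_with_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        t = gp.Transition(
            parents=gp.ParentPopulation(p=p, q=p.copy()),
            offspring_counts=rng.poisson(2, 30).astype(float),
        )
        with pytest.raises(gp.IdentifiabilityError):
            gp.fit_least_squares(t, gp.model_2())


class TestCoefficientTest:
    def test_term_not_in_spec_rejected(self):
        rng = np.random.default_rng(3)
        fit = gp.fit_least_squares(random_transition(rng, n=30), gp.model_a())
        with pytest.raises(gp.DomainError):
            gp.coefficient_test(fit, (2, 0))

    def test_exact_fit_degenerates_to_infinite_statistic(self, grid11):
        t = gp.Transition(
            parents=grid11, offspring_counts=1.0 + grid11.p, expected_mode=True
        )
        fit = gp.fit_least_squares(t, gp.model_a())
        stat, p = gp.coefficient_test(fit, (1, 0))
        assert np.isinf(stat) and p == 0.0

    def test_true_quadratic_effect_detected(self):
        cfg = gp.SimulationConfig(
            levels=GRID_LEVELS, count_per_level=200,
            model=gp.model_b().with_coefficients({(0, 0): 1.0, (1, 0): 0.0, (2, 0): 1.0}),
            seed=10,
        )
        fit = gp.fit_least_squares(gp.simulate_transition(cfg), gp.model_b())
        _, p = gp.coefficient_test(fit, (2, 0))
        assert p < 1e-6

    def test_spurious_quadratic_term_rarely_significant(self):
        """Overspecified quadratic fit on linear-truth data: the β₂ test should
        be non-significant at the 5% level in ≥90% of seeds."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = gp.SimulationConfig(
                levels=GRID_LEVELS, count_per_level=100,
                model=gp.model_a().with_coefficients({(0, 0): 1.0, (1, 0): 1.0}),
                seed=seed,
            )
            fit = gp.fit_least_squares(gp.simulate_transition(cfg), gp.model_b())
            _, p = gp.coefficient_test(fit, (2, 0))
            hits += p >= 0.05
        assert hits >= 0.9 * n_seeds


class TestUnbiasedness:
    def test_well_specified_estimates_unbiased(self):
        """Mean β̂ over 200 stochastic replicates within 3 MC SEs of the truth."""
        true = {(0, 0): 1.0, (1, 0): 1.0}
        model = gp.model_a().with_coefficients(true)
        rng = np.random.default_rng(123)
        pop = gp.make_grid_population(GRID_LEVELS, 50)
        draws = {term: [] for term in true}
        for _ in range(200):
            t = gp.transition_from_population(pop, model, seed=rng)
            fit = gp.fit_least_squares(t, gp.model_a())
            for term in true:
                draws[term].append(fit.beta_hat[term])
        for term, vals in draws.items():
            vals = np.asarray(vals)
            mc_se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - true[term]) < 3 * mc_se

    def test_overspecification_is_harmless(self):
        """Quadratic fit to linear truth: mean β̂₂ ≈ 0 across replicates."""
        model = gp.model_a().with_coefficients({(0, 0): 1.0, (1, 0): 1.0})
        rng = np.random.default_rng(77)
        pop = gp.make_grid_population(GRID_LEVELS, 50)
        b2 = []
        for _ in range(200):
            t = gp.transition_from_population(pop, model, seed=rng)
            b2.append(gp.fit_least_squares(t, gp.model_b()).beta_hat[(2, 0)])
        b2 = np.asarray(b2)
        mc_se = b2.std(ddof=1) / np.sqrt(b2.size)
        assert abs(b2.mean()) < 3 * mc_se
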