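"""Augmented Lagrangian solver: subproblem, updates, convergence, identification."""

import numpy as np
import pytest

from bifactor import (
    ALMConfig,
    ALMState,
    SampleCovariance,
    bifactor_distance,
    constraint_values,
    discrepancy_loss,
    emc,
    fit_multistart,
    fit_single_start,
    identify_solution,
    loading_mse,
    model_covariance,
    population_input,
)
from bifactor.alm import (
    _al_value_grad,
    beta_from_correlation,
    inner_minimize,
    random_start,
    update_multipliers,
    update_penalty,
)
from bifactor.constraints import n_constraints
from bifactor.core import build_group_correlation, pack_params

from conftest import exact_sigma_sample, random_params


def _state(params, sample, mu=1.0, multipliers=None, form="pairwise"):
    n = n_constraints(sample.J, params.G, form)
    m = np.zeros(n) if multipliers is None else multipliers
    return ALMState(params=params, multipliers=m, mu=mu, constraint_form=form)


class TestAugmentedLagrangian:
    def test_equals_loss_on_feasible_point_with_zero_multipliers(self, rng):
        from bifactor.alm import augmented_lagrangian

        p = random_params(rng, 6, 2)
        p.loadings.values[:, 2] = 0.0  # exact bi-factor: only group 1 loaded
        s = exact_sigma_sample(p)
        state = _state(p, s, mu=7.0)
        assert augmented_lagrangian(p, state, s) == pytest.approx(
            discrepancy_loss(p, s)
        )

    def test_single_constraint_arithmetic(self, rng):
        """c=0.3, multiplier=2, mu=4 adds 0.6 + 0.18 to the loss."""
        from bifactor.alm import augmented_lagrangian

        p = random_params(rng, 4, 2)
        p.loadings.values[:, 1:] = 0.0
        p.loadings.values[0, 1], p.loadings.values[0, 2] = 0.5, 0.6  # c = 0.3
        s = exact_sigma_sample(p)
        m = np.zeros(n_constraints(4, 2))
        m[0] = 2.0
        state = _state(p, s, mu=4.0, multipliers=m)
        expected = discrepancy_loss(p, s) + 2.0 * 0.3 + 0.5 * 4.0 * 0.09
        assert augmented_lagrangian(p, state, s) == pytest.approx(expected)

    def test_penalty_dominates_for_large_mu(self, rng):
        from bifactor.alm import augmented_lagrangian

        p = random_params(rng, 4, 2)  # generically infeasible
        s = exact_sigma_sample(p)
        vals = [
            augmented_lagrangian(p, _state(p, s, mu=mu), s)
            for mu in (1e2, 1e4, 1e6)
        ]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e3

    @pytest.mark.parametrize("form", ["pairwise", "row_aggregate"])
    def test_gradient_matches_finite_differences(self, rng, form):
        p = random_params(rng, 5, 3)
        s = exact_sigma_sample(random_params(rng, 5, 3))
        n = n_constraints(5, 3, form)
        m = rng.normal(size=n)
        mu = 3.0
        theta = pack_params(p)
        _, grad = _al_value_grad(theta, 5, 3, s, m, mu, form)
        step = 1e-6
        for k in range(theta.size):
            e = np.zeros_like(theta)
            e[k] = step
            hi, _ = _al_value_grad(theta + e, 5, 3, s, m, mu, form)
            lo, _ = _al_value_grad(theta - e, 5, 3, s, m, mu, form)
            assert grad[k] == pytest.approx((hi - lo) / (2 * step), rel=1e-4, abs=1e-7)


class TestUpdates:
    def test_multiplier_first_order_update(self, rng):
        p = random_params(rng, 4, 2)
        s = exact_sigma_sample(p)
        state = _state(p, s, mu=2.0)
        c = constraint_values(p.loadings, "pairwise").values
        updated = update_multipliers(state)
        np.testing.assert_allclose(updated, 2.0 * c)

    def test_feasible_point_leaves_multipliers_unchanged(self, rng):
        p = random_params(rng, 4, 2)
        p.loadings.values[:, 2] = 0.0
        s = exact_sigma_sample(p)
        state = _state(p, s, mu=5.0, multipliers=np.full(n_constraints(4, 2), 1.5))
        np.testing.assert_allclose(update_multipliers(state), 1.5)

    def test_penalty_growth_rule(self, rng):
        cfg = ALMConfig(gamma=0.25, rho=10.0, mu_max=50.0)
        p = random_params(rng, 4, 2)
        p.loadings.values[0, 1], p.loadings.values[0, 2] = 1.0, 0.2  # max|c|=0.2
        for row in range(1, 4):
            p.loadings.values[row, 1:] = 0.0
        s = exact_sigma_sample(p)
        state = _state(p, s, mu=1.0)
        assert update_penalty(state, prev_violation=1.0, config=cfg) == 1.0  # 0.2 <= 0.25
        assert update_penalty(state, prev_violation=0.5, config=cfg) == 10.0  # grew
        state.mu = 50.0
        assert update_penalty(state, prev_violation=0.01, config=cfg) == 50.0  # capped


class TestInnerMinimize:
    def test_stationary_start_stays_put(self, small_truth, small_population, fast_config):
        state = _state(small_truth.params, small_population)
        out = inner_minimize(state, small_population, fast_config)
        assert discrepancy_loss(out, small_population) == pytest.approx(0, abs=1e-10)

    def test_descent_and_gradient_tolerance(self, rng, fast_config):
        from bifactor.alm import augmented_lagrangian

        p_true = random_params(rng, 6, 2)
        s = exact_sigma_sample(p_true)
        start = random_start(s, 2, rng)
        state = _state(start, s, mu=1.0)
        before = augmented_lagrangian(start, state, s)
        out = inner_minimize(state, s, fast_config)
        after = augmented_lagrangian(out, state, s)
        assert after <= before
        _, grad = _al_value_grad(
            pack_params(out), 6, 2, s, state.multipliers, state.mu, "pairwise"
        )
        # omega components may rest on their conditioning bounds
        assert np.max(np.abs(grad[: 6 * 3 + 1])) <= 1e-5


class TestFitSingleStart:
    def test_population_recovery(self, small_truth, small_population, fast_config):
        """Each converged start is feasible; the best of a few reaches the
        global minimum and recovers the true structure (local minima are
        expected from single arbitrary starts)."""
        rng = np.random.default_rng(5)
        results = []
        for _ in range(4):
            start = random_start(small_population, 3, rng)
            res = fit_single_start(small_population, 3, fast_config, start)
            assert res.converged
            assert (
                bifactor_distance(res.params.loadings)
                < fast_config.tolerances.eps_struct
            )
            results.append(res)
        best = min(results, key=lambda r: r.loss)
        assert best.loss < 1e-6
        assert emc(small_truth.structure, best.structure) == 1

    def test_violation_driven_down(self, small_truth, small_population, fast_config):
        rng = np.random.default_rng(6)
        start = random_start(small_population, 3, rng)
        res = fit_single_start(small_population, 3, fast_config, start)
        hist = res.diagnostics
        assert hist[-1]["max_abs_c"] < 10 * fast_config.tolerances.eps_struct
        assert hist[-1]["max_abs_c"] <= hist[0]["max_abs_c"]

    def test_single_group_factor_unconstrained(self, rng, fast_config):
        p = random_params(rng, 6, 1)
        s = exact_sigma_sample(p)
        start = random_start(s, 1, rng)
        res = fit_single_start(s, 1, fast_config, start)
        assert res.converged
        assert res.loss < 1e-8


class TestFitMultistart:
    def test_seeded_determinism(self, small_population):
        cfg = ALMConfig.profile("simulation", n_starts=3, seed=42)
        r1 = fit_multistart(small_population, 3, cfg)
        r2 = fit_multistart(small_population, 3, cfg)
        np.testing.assert_array_equal(r1.params.loadings.values, r2.params.loadings.values)
        np.testing.assert_array_equal(r1.params.uniq.psi, r2.params.uniq.psi)
        assert r1.start_objectives == r2.start_objectives

    def test_winner_is_minimum_over_starts(self, small_fit):
        assert small_fit.loss == pytest.approx(min(small_fit.start_objectives))
        assert small_fit.n_starts_used == 5

    def test_mu_stays_bounded_on_solvable_instance(self, small_fit):
        assert all(h["mu"] < 1e8 for h in small_fit.diagnostics)


class TestIdentifySolution:
    def test_model_covariance_invariant(self, rng):
        import warnings as _warnings

        p = random_params(rng, 9, 3)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)  # infeasible test point
            q = identify_solution(p)
        np.testing.assert_allclose(
            model_covariance(p), model_covariance(q), atol=1e-12
        )

    def test_canonical_fixed_point_and_involution(self, small_truth):
        p = identify_solution(small_truth.params)
        again = identify_solution(p)
        np.testing.assert_allclose(p.loadings.values, again.loadings.values, atol=1e-12)
        flipped = p.copy()
        flipped.loadings.values[:, 1] *= -1
        phi = build_group_correlation(flipped.corr_params, 3)
        phi[0, 1:] *= -1
        phi[1:, 0] *= -1
        flipped.corr_params.beta = beta_from_correlation(phi)
        restored = identify_solution(flipped)
        np.testing.assert_allclose(
            restored.loadings.values, p.loadings.values, atol=1e-10
        )

    def test_beta_round_trip(self, rng):
        from bifactor.core import n_free_beta

        beta = rng.normal(size=n_free_beta(4))
        phi = build_group_correlation(beta, 4)
        np.testing.assert_allclose(
            build_group_correlation(beta_from_correlation(phi), 4), phi, atol=1e-12
        )


class TestPopulationRecoveryProperty:
    def test_twenty_random_exact_models(self, fast_config):
        """Identifiability analog: S = Sigma0 recovers structure and loadings."""
        from bifactor import SimulationDesign, check_condition3, generate_exact_model

        cfg = ALMConfig.profile("simulation", n_starts=6, seed=9)
        for seed in range(8):
            truth = generate_exact_model(SimulationDesign(J=15, G=3, N=500, seed=seed))
            assert check_condition3(truth)[0]
            samp = population_input(truth)
            res = fit_multistart(samp, 3, cfg)
            assert res.converged
            assert emc(truth.structure, res.structure) == 1
            ident = identify_solution(res.params)
            assert loading_mse(truth.params.loadings, ident.loadings) < 1e-4
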