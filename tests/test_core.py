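"""Model covariance, correlation reparameterization, discrepancy and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bifactor import (
    BiFactorParams,
    GroupCorrelationParams,
    LoadingMatrix,
    SampleCovariance,
    Uniquenesses,
    build_group_correlation,
    build_phi,
    discrepancy_loss,
    loss_gradient,
    model_covariance,
)
from bifactor.core import n_free_beta, pack_params, unpack_params

from conftest import exact_sigma_sample, random_params, random_sample


class TestGroupCorrelation:
    @pytest.mark.parametrize(
        "G, beta, expected",
        [
            (1, [], np.eye(1)),
            (2, [0.0], np.eye(2)),
            (2, [1.0], np.array([[1.0, 1 / np.sqrt(2)], [1 / np.sqrt(2), 1.0]])),
        ],
    )
    def test_known_values(self, G, beta, expected):
        np.testing.assert_allclose(build_group_correlation(beta, G), expected, atol=1e-14)

    def test_dimension_mismatch_names_expected_length(self):
        with pytest.raises(ValueError, match="G\\(G-1\\)/2 = 3"):
            build_group_correlation([0.1, 0.2], 3)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        G=st.integers(min_value=1, max_value=10),
        seed=st.integers(min_value=0, max_value=10_000),
        scale=st.floats(min_value=0.01, max_value=30.0),
    )
    def test_always_a_correlation_matrix(self, G, seed, scale):
        """Every finite beta maps to a unit-diagonal symmetric PD matrix."""
        beta = scale * np.random.default_rng(seed).normal(size=n_free_beta(G))
        phi = build_group_correlation(beta, G)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-12)
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        # PD by construction; near-collinear rows at extreme beta can push the
        # smallest eigenvalue to the round-off floor
        assert np.linalg.eigvalsh(phi)[0] > -1e-10


class TestBuildPhi:
    def test_general_factor_uncorrelated_with_groups(self):
        phi = build_phi([1.0], 2)
        np.testing.assert_allclose(phi[0], [1.0, 0.0, 0.0])
        assert phi[1, 2] == pytest.approx(1 / np.sqrt(2))

    def test_zero_beta_gives_identity(self):
        np.testing.assert_allclose(build_phi(np.zeros(3), 3), np.eye(4))


class TestModelCovariance:
    def test_zero_loadings_unit_psi_gives_identity(self):
        p = BiFactorParams(
            LoadingMatrix(np.zeros((4, 3))),
            GroupCorrelationParams([0.0]),
            Uniquenesses(np.ones(4)),
        )
        np.testing.assert_allclose(model_covariance(p), np.eye(4))

    def test_single_factor_example(self):
        p = BiFactorParams(
            LoadingMatrix(np.array([[1.0, 0.0], [1.0, 0.0]])),
            GroupCorrelationParams([]),
            Uniquenesses(np.ones(2)),
        )
        np.testing.assert_allclose(model_covariance(p), [[2.0, 1.0], [1.0, 2.0]])

    def test_low_rank_plus_diagonal(self, rng):
        p = random_params(rng, J=8, G=2)
        sigma = model_covariance(p)
        resid = sigma - np.diag(p.uniq.psi)
        assert np.linalg.matrix_rank(resid, tol=1e-8) <= p.G + 1


class TestDiscrepancy:
    def test_zero_at_truth(self, rng):
        p = random_params(rng, J=6, G=2)
        assert discrepancy_loss(p, exact_sigma_sample(p)) == pytest.approx(0, abs=1e-10)

    def test_scaled_identity_value(self):
        """S = I2, Sigma = 2 I2 gives 2 log 2 - 1."""
        p = BiFactorParams(
            LoadingMatrix(np.zeros((2, 2))),
            GroupCorrelationParams([]),
            Uniquenesses(np.full(2, 2.0)),
        )
        s = SampleCovariance(S=np.eye(2), N=10)
        assert discrepancy_loss(p, s) == pytest.approx(2 * np.log(2) - 1)

    def test_nonnegative_and_zero_iff_match(self, rng):
        for _ in range(20):
            p = random_params(rng, J=5, G=2)
            s = random_sample(rng, J=5)
            loss = discrepancy_loss(p, s)
            assert loss >= 0
            match = np.allclose(model_covariance(p), s.S, atol=1e-10)
            assert (loss < 1e-10) == match

    def test_singular_sample_reports_condition_number(self):
        p = BiFactorParams(
            LoadingMatrix(np.zeros((3, 2))),
            GroupCorrelationParams([]),
            Uniquenesses(np.ones(3)),
        )
        S = np.ones((3, 3))  # rank 1
        sample = SampleCovariance(S=S, N=10)
        with pytest.raises(Exception, match="condition number"):
            discrepancy_loss(p, sample)

    def test_matches_neg2_loglik_up_to_constant(self, rng):
        """N*loss differences equal -2*loglik differences across parameter pairs."""
        J, G, N = 5, 2, 40
        truth = random_params(rng, J, G)
        X = rng.multivariate_normal(np.zeros(J), model_covariance(truth), size=N)
        sample = SampleCovariance.from_data(X, denominator="ml")
        Xc = X - X.mean(axis=0)
        for _ in range(5):
            p1, p2 = random_params(rng, J, G), random_params(rng, J, G)
            d_loss = N * (
                discrepancy_loss(p1, sample) - discrepancy_loss(p2, sample)
            )
            ll1 = stats.multivariate_normal(np.zeros(J), model_covariance(p1)).logpdf(Xc).sum()
            ll2 = stats.multivariate_normal(np.zeros(J), model_covariance(p2)).logpdf(Xc).sum()
            assert d_loss == pytest.approx(-2 * (ll1 - ll2), rel=1e-8)


class TestGradient:
    def test_zero_loading_gradient_at_global_minimum(self, rng):
        p = random_params(rng, J=6, G=2)
        g_lam, g_beta, g_omega = loss_gradient(p, exact_sigma_sample(p))
        np.testing.assert_allclose(g_lam, 0, atol=1e-9)
        np.testing.assert_allclose(g_beta, 0, atol=1e-9)
        np.testing.assert_allclose(g_omega, 0, atol=1e-9)

    def test_omega_gradient_is_psi_times_psi_gradient(self, rng):
        """Chain-rule identity through psi = exp(omega)."""
        p = random_params(rng, J=5, G=2)
        s = random_sample(rng, J=5)
        _, _, g_omega = loss_gradient(p, s)
        eps = 1e-7
        for j in range(3):
            psi_hi, psi_lo = p.uniq.psi.copy(), p.uniq.psi.copy()
            psi_hi[j] += eps
            psi_lo[j] -= eps
            hi = discrepancy_loss(
                BiFactorParams(p.loadings, p.corr_params, Uniquenesses(psi_hi)), s
            )
            lo = discrepancy_loss(
                BiFactorParams(p.loadings, p.corr_params, Uniquenesses(psi_lo)), s
            )
            dl_dpsi = (hi - lo) / (2 * eps)
            assert g_omega[j] == pytest.approx(p.uniq.psi[j] * dl_dpsi, rel=1e-4)

    @pytest.mark.parametrize("J,G", [(6, 2), (8, 3), (5, 1)])
    def test_matches_central_finite_differences(self, rng, J, G):
        s = random_sample(rng, J=J)
        p = random_params(rng, J=J, G=G)
        theta = pack_params(p)
        g_lam, g_beta, g_omega = loss_gradient(p, s)
        grad = np.concatenate([g_lam.ravel(), g_beta, g_omega])
        step = 1e-6
        for k in range(theta.size):
            e = np.zeros_like(theta)
            e[k] = step
            num = (
                discrepancy_loss(unpack_params(theta + e, J, G), s)
                - discrepancy_loss(unpack_params(theta - e, J, G), s)
            ) / (2 * step)
            assert grad[k] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestSampleCovariance:
    def test_rejects_asymmetric(self):
        M = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            SampleCovariance(S=M, N=10)

    def test_ml_vs_unbiased_denominator(self, rng):
        X = rng.normal(size=(50, 4))
        s_ml = SampleCovariance.from_data(X, denominator="ml")
        s_ub = SampleCovariance.from_data(X, denominator="unbiased")
        np.testing.assert_allclose(s_ub.S * 49 / 50, s_ml.S)

    def test_correlation_flag_standardizes(self, rng):
        X = rng.normal(size=(100, 3)) * np.array([1.0, 5.0, 0.2])
        s = SampleCovariance.from_data(X, is_correlation=True)
        np.testing.assert_allclose(np.diag(s.S), 1.0)
        assert s.is_correlation
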