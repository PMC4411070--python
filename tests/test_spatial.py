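"""Kernel, coefficient-covariance and matrix-normal machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import multivariate_normal

from pondsvc.spatial import (
    DistanceMatrix,
    KernelParams,
    NumericalError,
    build_T,
    cholesky_with_jitter,
    cpc_to_correlation,
    gaussian_correlation,
    lkj_log_normalizer,
    lkj_logpdf,
    matrix_normal_logpdf,
    sample_lkj,
)


def random_pd(rng, d, scale=1.0):
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))


class TestGaussianCorrelation:
    def test_zero_distance_is_one(self):
        assert gaussian_correlation(0.01, np.array(0.0)) == 1.0

    def test_phi_constructed_to_hit_correlation(self):
        phi = np.sqrt(-np.log(0.05)) / 500
        assert gaussian_correlation(phi, np.array(500.0)) == pytest.approx(
            0.05, abs=1e-15
        )

    def test_three_strata_matrix_values(self):
        D = DistanceMatrix(
            np.array([[0, 100, 300], [100, 0, 200], [300, 200, 0]], dtype=float)
        )
        K = gaussian_correlation(0.002, D)
        # direct scalar evaluation of exp(-phi^2 d^2)
        assert K[0, 1] == pytest.approx(0.9607894391523232, abs=1e-12)
        assert K[0, 2] == pytest.approx(0.6976763260710347, abs=1e-12)
        assert K[1, 2] == pytest.approx(0.8521437889662113, abs=1e-12)
        assert np.all(np.diag(K) == 1.0)
        assert np.all(K == K.T)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            gaussian_correlation(0.0, np.array(1.0))
        with pytest.raises(ValueError):
            KernelParams(phi=-1.0)

    def test_asymmetric_distances_rejected(self):
        with pytest.raises(ValueError):
            gaussian_correlation(0.01, np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        phi=st.floats(1e-4, 8e-3),
        d1=st.floats(1.0, 800.0),
        delta=st.floats(1.0, 200.0),
    )
    def test_strictly_decreasing_in_distance_and_phi(self, phi, d1, delta):
        k_near = gaussian_correlation(phi, np.array(d1))
        k_far = gaussian_correlation(phi, np.array(d1 + delta))
        assert k_far < k_near
        assert gaussian_correlation(phi * 1.5, np.array(d1)) < k_near


class TestBuildT:
    def test_identity_case(self):
        cov = build_T(np.ones(2), np.eye(2))
        assert np.allclose(cov.T, np.eye(2))

    def test_two_by_two_arithmetic(self):
        rho = np.array([[1.0, 0.5], [0.5, 1.0]])
        cov = build_T(np.array([2.0, 3.0]), rho)
        assert np.allclose(cov.T, [[4.0, 3.0], [3.0, 9.0]])

    def test_positive_definite_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = int(rng.integers(2, 6))
            rho = sample_lkj(d, 1.0, rng)
            sigma = rng.uniform(0.1, 3.0, d)
            eig = np.linalg.eigvalsh(build_T(sigma, rho).T)
            assert np.all(eig > 0)

    def test_round_trip_recovers_sigma_and_rho(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = int(rng.integers(2, 7))
            rho = sample_lkj(d, 1.0, rng)
            sigma = rng.uniform(0.05, 4.0, d)
            T = build_T(sigma, rho).T
            sigma_back = np.sqrt(np.diag(T))
            rho_back = T / np.outer(sigma_back, sigma_back)
            assert np.allclose(sigma_back, sigma, atol=1e-12)
            assert np.allclose(rho_back, rho, atol=1e-12)

    def test_non_pd_rho_rejected(self):
        rho = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            build_T(np.ones(3), rho)


class TestMatrixNormal:
    def test_standard_normal_at_mode(self):
        S, P = 5, 3
        val = matrix_normal_logpdf(np.zeros((S, P)), np.eye(S), np.eye(P))
        assert val == pytest.approx(-(S * P / 2) * np.log(2 * np.pi), abs=1e-12)

    def test_matches_vectorized_kronecker_mvn(self):
        rng = np.random.default_rng(3)
        S, P = 4, 3
        K = random_pd(rng, S)
        T = random_pd(rng, P)
        W = rng.standard_normal((S, P))
        ours = matrix_normal_logpdf(W, K, T)
        # vec in stratum-major order matches cov K (x) T
        oracle = multivariate_normal.logpdf(
            W.reshape(-1), mean=np.zeros(S * P), cov=np.kron(K, T)
        )
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_kronecker_scale_invariance(self):
        rng = np.random.default_rng(4)
        K = random_pd(rng, 4)
        T = random_pd(rng, 2)
        W = rng.standard_normal((4, 2))
        for c in (0.1, 3.7):
            assert matrix_normal_logpdf(W, c * K, T / c) == pytest.approx(
                matrix_normal_logpdf(W, K, T), abs=1e-9
            )

    def test_accepts_coefficient_covariance(self):
        rng = np.random.default_rng(5)
        cov = build_T(np.array([1.0, 2.0]), np.eye(2))
        W = rng.standard_normal((3, 2))
        assert matrix_normal_logpdf(W, np.eye(3), cov) == pytest.approx(
            matrix_normal_logpdf(W, np.eye(3), cov.T)
        )


class TestLKJ:
    def test_two_by_two_uniform_value(self):
        for r in (-0.8, 0.0, 0.63):
            rho = np.array([[1.0, r], [r, 1.0]])
            assert lkj_logpdf(rho, eta=1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_three_by_three_normalizer_is_elliptope_volume(self):
        # the space of 3x3 correlation matrices has volume pi^2/2
        assert lkj_log_normalizer(3, 1.0) == pytest.approx(
            np.log(2.0 / np.pi**2), abs=1e-12
        )

    def test_identity_finite_any_dimension(self):
        for d in (2, 4, 7):
            assert np.isfinite(lkj_logpdf(np.eye(d), eta=1.0))

    def test_flat_over_random_valid_matrices(self):
        rng = np.random.default_rng(6)
        vals = [lkj_logpdf(sample_lkj(3, 1.0, rng), eta=1.0) for _ in range(100)]
        assert np.std(vals) < 1e-12

    def test_eta_weights_determinant(self):
        rho = cpc_to_correlation(
            np.array([[0, 0.5, 0.2], [0, 0, -0.3], [0, 0, 0]], dtype=float)
        )
        expected_shift = 1.5 * np.linalg.slogdet(rho)[1]
        shift = (lkj_logpdf(rho, 2.5) - lkj_log_normalizer(3, 2.5)) - (
            lkj_logpdf(rho, 1.0) - lkj_log_normalizer(3, 1.0)
        )
        assert shift == pytest.approx(expected_shift, abs=1e-12)

    def test_unit_diagonal_violation_rejected(self):
        bad = np.array([[1.1, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            lkj_logpdf(bad)

    def test_sampled_matrices_are_valid(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rho = sample_lkj(5, 1.0, rng)
            assert np.allclose(np.diag(rho), 1.0)
            assert np.linalg.eigvalsh(rho)[0] > 0


class TestCholeskyJitter:
    def test_recovers_near_singular(self):
        a = np.ones((3, 3)) + 1e-12 * np.eye(3)
        L = cholesky_with_jitter(a)
        assert np.all(np.isfinite(L))

    def test_indefinite_matrix_reports_condition(self):
        with pytest.raises(NumericalError, match="condition"):
            cholesky_with_jitter(np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_distance_matrix_from_centroids_round_trip():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 1000, (6, 2))
    D = DistanceMatrix(squareform(pdist(pts)))
    assert D.n_strata == 6
    assert D.offdiagonal().shape == (15,)
    assert np.all(D.offdiagonal() > 0)
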