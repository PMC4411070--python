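"""Linear predictor, observation likelihood, priors and joint posterior."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, lognorm, norm

import pondsvc as p
from pondsvc.model import (
    GAMMA_RATE,
    GAMMA_SHAPE,
    DesignPanel,
    SVCParameters,
    log_posterior_parts,
)
from pondsvc.spatial import DistanceMatrix, sample_lkj

from conftest import exogenous_panel


def tiny_panel(S=3, Y=4, P=2, seed=0, areas=None):
    """Small panel with exogenous covariates and given areas."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((S, Y - 1, P))
    X = np.concatenate([np.ones((S, Y - 1, 1)), Z], axis=2)
    ponds = np.exp(rng.normal(2.0, 0.5, (S, Y)))
    offset = np.zeros(S) if areas is None else np.log(areas)
    return DesignPanel(
        ponds=ponds,
        X=X,
        offset=offset,
        years=np.arange(Y),
        predictor_names=["intercept"] + [f"x{i}" for i in range(P)],
    )


def zero_params(S, P, tau=0.5, phi=0.003):
    return SVCParameters(
        mu0=0.0,
        mu_beta=np.zeros(P),
        w0=np.zeros(S),
        W=np.zeros((S, P)),
        sigma_beta0=1.0,
        sigma_beta=np.ones(P),
        tau=np.full(S, tau),
        rho=np.eye(P),
        phi0=phi,
        phiB=phi,
    )


class TestLinearPredictor:
    def test_offset_plus_constant(self):
        panel = tiny_panel(areas=np.full(3, np.e**3))
        params = zero_params(3, 2)
        params.mu0 = 2.0
        mu = p.linear_predictor(params, panel)
        assert np.allclose(mu, 5.0)

    def test_single_predictor_arithmetic(self):
        panel = tiny_panel()
        panel.X[:, :, 1] = 1.5
        params = zero_params(3, 2)
        params.mu_beta = np.array([1.2, 0.0])
        params.W[:, 0] = 0.8
        mu = p.linear_predictor(params, panel)
        assert np.allclose(mu, 1.5 * 2.0)

    def test_doubling_area_adds_log_two(self):
        base = tiny_panel(areas=np.full(3, 100.0))
        doubled = tiny_panel(areas=np.full(3, 200.0))
        params = zero_params(3, 2)
        params.mu_beta = np.array([0.3, -0.2])
        assert np.allclose(
            p.linear_predictor(params, doubled) - p.linear_predictor(params, base),
            np.log(2.0),
        )

    def test_shape_mismatch_rejected(self):
        panel = tiny_panel(S=3, P=2)
        with pytest.raises(ValueError, match="do not match"):
            p.linear_predictor(zero_params(4, 2), panel)


class TestObservationLoglik:
    def test_single_cell_at_log_scale_mode(self):
        # pond = e^mu: density is -ln tau - 0.5 ln 2pi - mu (the -mu is the
        # 1/x Jacobian of the lognormal)
        mu_val, tau = 1.7, 0.4
        panel = tiny_panel(S=1, Y=2, P=1)
        panel.ponds[0, 1] = np.exp(mu_val)
        ll = p.observation_loglik(
            panel, np.full((1, 1), mu_val), np.array([tau])
        )
        expected = -np.log(tau) - 0.5 * np.log(2 * np.pi) - mu_val
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_scalar_value_against_scipy(self):
        panel = tiny_panel(S=1, Y=2, P=1)
        panel.ponds[0, 1] = 100.0
        ll = p.observation_loglik(
            panel, np.full((1, 1), np.log(100.0)), np.array([0.5])
        )
        oracle = lognorm.logpdf(100.0, s=0.5, scale=100.0)
        assert ll == pytest.approx(oracle, abs=1e-12)
        assert ll == pytest.approx(-4.8310, abs=5e-5)

    def test_additivity_over_cells(self):
        panel = tiny_panel(S=3, Y=5, P=2, seed=4)
        params = zero_params(3, 2, tau=0.7)
        mu = p.linear_predictor(params, panel)
        total = p.observation_loglik(panel, mu, params.tau)
        acc = 0.0
        for s in range(3):
            single = tiny_panel(S=1, Y=5, P=2)
            single.ponds[0] = panel.ponds[s]
            acc += p.observation_loglik(
                single, mu[s : s + 1], params.tau[s : s + 1]
            )
        assert total == pytest.approx(acc, abs=1e-9)

    def test_nonpositive_tau_rejected(self):
        panel = tiny_panel()
        with pytest.raises(ValueError, match="tau"):
            p.observation_loglik(panel, np.zeros((3, 3)), np.array([0.5, -1.0, 0.5]))


class TestPhiPriorBounds:
    def test_closed_form_example(self):
        D = DistanceMatrix(
            np.array([[0, 100, 1000], [100, 0, 990], [1000, 990, 0]], dtype=float)
        )
        b = p.phi_prior_bounds(D)
        assert b.lower == pytest.approx(np.sqrt(0.1053605) / 1000, rel=1e-5)
        assert b.upper == pytest.approx(np.sqrt(4.6051702) / 100, rel=1e-5)
        assert b.lower == pytest.approx(3.246e-4, rel=1e-3)
        assert b.upper == pytest.approx(2.146e-2, rel=1e-3)

    def test_round_trips_by_construction(self):
        D = DistanceMatrix(
            np.array([[0, 150, 800], [150, 0, 700], [800, 700, 0]], dtype=float)
        )
        b = p.phi_prior_bounds(D)
        off = D.offdiagonal()
        d_min, d_max = off.min(), off.max()
        assert p.gaussian_correlation(b.lower, np.array(d_max)) == pytest.approx(
            0.90, abs=1e-12
        )
        assert p.gaussian_correlation(b.upper, np.array(d_min)) == pytest.approx(
            0.01, abs=1e-12
        )

    def test_degenerate_distances_rejected(self):
        D = DistanceMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="smallest"):
            p.phi_prior_bounds(D)


class TestLogPrior:
    def test_hyperprior_matches_scipy_sum(self, geometry8):
        rng = np.random.default_rng(9)
        S, P = 8, 3
        bounds = p.phi_prior_bounds(geometry8.D)
        params = SVCParameters(
            mu0=rng.normal(),
            mu_beta=rng.normal(size=P),
            w0=rng.normal(size=S),
            W=rng.normal(size=(S, P)),
            sigma_beta0=rng.uniform(0.5, 3),
            sigma_beta=rng.uniform(0.5, 3, P),
            tau=rng.uniform(0.2, 1.0, S),
            rho=sample_lkj(P, 1.0, rng),
            phi0=rng.uniform(bounds.lower, bounds.upper),
            phiB=rng.uniform(bounds.lower, bounds.upper),
        )
        lp = p.log_prior(params, bounds, include_fields=False)
        span = bounds.upper - bounds.lower
        manual = (
            norm.logpdf(params.mu0, 0, 10)
            + norm.logpdf(params.mu_beta, 0, 10).sum()
            + gamma_dist.logpdf(
                params.sigma_beta0, GAMMA_SHAPE, scale=1 / GAMMA_RATE
            )
            + gamma_dist.logpdf(
                params.sigma_beta, GAMMA_SHAPE, scale=1 / GAMMA_RATE
            ).sum()
            + gamma_dist.logpdf(params.tau, GAMMA_SHAPE, scale=1 / GAMMA_RATE).sum()
            + p.lkj_logpdf(params.rho, 1.0)
            - 2 * np.log(span)
        )
        assert lp == pytest.approx(manual, abs=1e-10)

    def test_gamma_prior_moments(self):
        # shape 1.2, rate 0.2: mean 6, sd sqrt(1.2)/0.2
        assert GAMMA_SHAPE / GAMMA_RATE == pytest.approx(6.0)
        assert np.sqrt(GAMMA_SHAPE) / GAMMA_RATE == pytest.approx(5.477, abs=1e-3)

    def test_phi_outside_support_is_minus_inf(self, geometry8):
        bounds = p.phi_prior_bounds(geometry8.D)
        params = zero_params(8, 2, phi=bounds.upper * 1.5)
        assert p.log_prior(params, bounds, include_fields=False) == -np.inf


class TestLogPosterior:
    def test_equals_sum_of_parts(self, geometry8):
        panel = exogenous_panel(geometry8, 10, 2, seed=21)
        rng = np.random.default_rng(22)
        bounds = p.phi_prior_bounds(geometry8.D)
        params = zero_params(8, 2, phi=0.5 * (bounds.lower + bounds.upper))
        params.mu_beta = rng.normal(size=2)
        params.w0 = rng.normal(size=8) * 0.3
        params.W = rng.normal(size=(8, 2)) * 0.2
        parts = log_posterior_parts(params, panel, geometry8.D)
        assert p.log_posterior(params, panel, geometry8.D) == pytest.approx(
            sum(parts.values()), abs=1e-10
        )
        assert set(parts) == {
            "hyper_prior",
            "intercept_field",
            "coefficient_field",
            "loglik",
        }

    def test_tau_far_from_residual_scale_decreases_posterior(self, study12):
        geometry, _, truth = study12
        at_truth = p.log_posterior(truth.params, truth.panel, geometry.D)
        inflated = SVCParameters(
            **{
                **truth.params.__dict__,
                "tau": truth.params.tau * 12.0,
            }
        )
        deflated = SVCParameters(
            **{
                **truth.params.__dict__,
                "tau": truth.params.tau / 12.0,
            }
        )
        assert p.log_posterior(inflated, truth.panel, geometry.D) < at_truth
        assert p.log_posterior(deflated, truth.panel, geometry.D) < at_truth

    def test_noncentered_map_differs_by_constant_jacobian(self, geometry8):
        """For fixed hyperparameters the centered log-posterior evaluated at
        mapped innovations minus the standard-normal density of those
        innovations is constant in the innovations."""
        panel = exogenous_panel(geometry8, 10, 2, seed=23)
        bounds = p.phi_prior_bounds(geometry8.D)
        phi = 0.5 * (bounds.lower + bounds.upper)
        rng = np.random.default_rng(24)
        sigma_beta = np.array([0.4, 0.9])
        rho = np.array([[1.0, 0.3], [0.3, 1.0]])
        deltas = []
        for _ in range(3):
            z0 = rng.standard_normal(8)
            Z = rng.standard_normal((8, 2))
            w0, W = p.noncentered_effects(
                z0, Z, 1.3, sigma_beta, rho, phi, phi, geometry8.D
            )
            params = SVCParameters(
                mu0=0.5,
                mu_beta=np.array([0.2, -0.1]),
                w0=w0,
                W=W,
                sigma_beta0=1.3,
                sigma_beta=sigma_beta,
                tau=np.full(8, 0.6),
                rho=rho,
                phi0=phi,
                phiB=phi,
            )
            lp_c = p.log_posterior(params, panel, geometry8.D)
            # subtract the z-dependent pieces of the non-centered density:
            # the likelihood at the mapped fields and the standard-normal
            # quadratic of the innovations; what remains is the constant
            # Jacobian/normalization gap between the parameterizations
            mu = p.linear_predictor(params, panel)
            ll = p.observation_loglik(panel, mu, params.tau)
            deltas.append(lp_c - ll + 0.5 * (z0 @ z0 + np.sum(Z * Z)))
        assert np.ptp(deltas) < 1e-8


class TestDesignPanelValidation:
    def test_lag_consistency_enforced(self):
        panel = tiny_panel(S=2, Y=4, P=1)
        X = np.concatenate([panel.X, panel.X[:, :, 1:]], axis=2)
        X[:, :, 1] = np.log(panel.ponds[:, :-1])
        DesignPanel(
            ponds=panel.ponds,
            X=X,
            offset=panel.offset,
            years=panel.years,
            predictor_names=["intercept", "log_lag", "x0"],
        )
        X_bad = X.copy()
        X_bad[0, 1, 1] += 0.5
        with pytest.raises(ValueError, match="lag"):
            DesignPanel(
                ponds=panel.ponds,
                X=X_bad,
                offset=panel.offset,
                years=panel.years,
                predictor_names=["intercept", "log_lag", "x0"],
            )

    def test_intercept_column_enforced(self):
        panel = tiny_panel()
        X = panel.X.copy()
        X[0, 0, 0] = 2.0
        with pytest.raises(ValueError, match="intercept"):
            DesignPanel(
                ponds=panel.ponds,
                X=X,
                offset=panel.offset,
                years=panel.years,
                predictor_names=panel.predictor_names,
            )

    def test_nonpositive_ponds_rejected(self):
        panel = tiny_panel()
        ponds = panel.ponds.copy()
        ponds[1, 2] = 0.0
        with pytest.raises(ValueError, match="positive"):
            DesignPanel(
                ponds=ponds,
                X=panel.X,
                offset=panel.offset,
                years=panel.years,
                predictor_names=panel.predictor_names,
            )
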