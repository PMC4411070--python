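"""Joint model of annual pond abundance with spatially varying coefficients.

Observation model: visibility-corrected pond totals in stratum s, survey
year t are lognormal,

    Pond_{s,t} ~ LN(mu_{s,t}, tau_s),

with log-scale mean

    mu_{s,t} = (mu_0 + w0_s)
             + sum_p (mu_beta_p + w_{s,p}) * x_{s,t,p}
             + log(area_s),

so the intercept is on the density (per km^2) scale.  The stratum intercept
deviations w0 follow a Gaussian-kernel multivariate normal with their own
decay phi_0; the predictor-coefficient deviations W follow a separable
matrix normal MN(0, K_B(phi_B), T(sigma_beta, rho)).

Priors: Normal(0, 10) on mu_0 and each mu_beta; Gamma(shape 1.2, rate 0.2)
on every sd (sigma_beta0, each sigma_beta, each tau_s); LKJ(1) on rho; and
uniform on phi_0, phi_B over bounds chosen so the kernel spans a
correlation of 0.90 at the largest inter-stratum distance down to 0.01 at
the smallest.

The first survey year enters only as the lag source and is excluded from
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import gamma as gamma_dist

from .spatial import (
    CoefficientCovariance,
    DistanceMatrix,
    build_T,
    cholesky_with_jitter,
    gaussian_correlation,
    lkj_logpdf,
    matrix_normal_logpdf,
)

__all__ = [
    "DesignPanel",
    "SVCParameters",
    "PhiBounds",
    "GAMMA_SHAPE",
    "GAMMA_RATE",
    "MU_PRIOR_SD",
    "linear_predictor",
    "observation_loglik",
    "phi_prior_bounds",
    "log_prior",
    "log_posterior",
    "log_posterior_parts",
    "noncentered_effects",
]

_LOG_2PI = np.log(2.0 * np.pi)

# Hyperprior constants: Normal(0, 10) on coefficient means (sd, not
# variance); Gamma(1.2, rate 0.2) on every standard deviation, so the prior
# mean of each scale is 6 and the prior sd is sqrt(1.2)/0.2.
MU_PRIOR_SD = 10.0
GAMMA_SHAPE = 1.2
GAMMA_RATE = 0.2

#: Predictor name marking the autoregressive lag column; its consistency
#: with the pond panel is validated when present.
LAG_NAME = "log_lag"


@dataclass
class DesignPanel:
    """Stratum x year panel of pond counts and the design array.

    ``ponds`` covers all Y survey years; ``X`` covers the Y-1 modeled years
    (the first year is consumed as the lag source).  Column 0 of ``X`` is
    the intercept; the offset is the per-stratum log area in log km^2.
    """

    ponds: np.ndarray  # (S, Y), strictly positive
    X: np.ndarray  # (S, Y-1, P_total)
    offset: np.ndarray  # (S,)
    years: np.ndarray  # (Y,)
    predictor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ponds = np.asarray(self.ponds, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.years = np.asarray(self.years)
        S, Y = self.ponds.shape
        if np.any(~np.isfinite(self.ponds)) or np.any(self.ponds <= 0):
            raise ValueError("pond counts must be finite and strictly positive")
        if self.X.shape[0] != S or self.X.shape[1] != Y - 1:
            raise ValueError(
                f"X must be (S, Y-1, P); got {self.X.shape} for S={S}, Y={Y}"
            )
        if not np.all(self.X[:, :, 0] == 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design array has non-finite entries")
        if self.offset.shape != (S,):
            raise ValueError("offset must be one log-area per stratum")
        if len(self.predictor_names) != self.X.shape[2]:
            raise ValueError("predictor_names length must match design columns")
        if self.predictor_names and self.predictor_names[0] != "intercept":
            raise ValueError("first predictor must be named 'intercept'")
        if LAG_NAME in self.predictor_names:
            j = self.predictor_names.index(LAG_NAME)
            expected = np.log(self.ponds[:, :-1])
            if not np.allclose(self.X[:, :, j], expected, atol=1e-8):
                raise ValueError(
                    "lag predictor must equal log ponds of the previous year"
                )

    @property
    def n_strata(self) -> int:
        return self.ponds.shape[0]

    @property
    def n_years(self) -> int:
        return self.ponds.shape[1]

    @property
    def n_modeled_years(self) -> int:
        return self.ponds.shape[1] - 1

    @property
    def n_predictors(self) -> int:
        """Non-intercept predictor count."""
        return self.X.shape[2] - 1

    @property
    def modeled_years(self) -> np.ndarray:
        return self.years[1:]

    @property
    def log_ponds_modeled(self) -> np.ndarray:
        """Log pond counts for the modeled years, (S, Y-1)."""
        return np.log(self.ponds[:, 1:])


@dataclass
class SVCParameters:
    """Every unknown of the posterior.

    ``W`` excludes the intercept column; the intercept field is ``w0``.
    """

    mu0: float
    mu_beta: np.ndarray  # (P,)
    w0: np.ndarray  # (S,)
    W: np.ndarray  # (S, P)
    sigma_beta0: float
    sigma_beta: np.ndarray  # (P,)
    tau: np.ndarray  # (S,)
    rho: np.ndarray  # (P, P)
    phi0: float
    phiB: float

    def __post_init__(self) -> None:
        self.mu_beta = np.atleast_1d(np.asarray(self.mu_beta, dtype=float))
        self.w0 = np.asarray(self.w0, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.sigma_beta = np.atleast_1d(np.asarray(self.sigma_beta, dtype=float))
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        S, P = self.W.shape
        if self.mu_beta.shape != (P,) or self.sigma_beta.shape != (P,):
            raise ValueError("mu_beta/sigma_beta must have one entry per predictor")
        if self.w0.shape != (S,) or self.tau.shape != (S,):
            raise ValueError("w0/tau must have one entry per stratum")
        if self.rho.shape != (P, P):
            raise ValueError("rho must be P x P")

    @property
    def n_strata(self) -> int:
        return self.W.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.W.shape[1]

    def coefficient_field(self) -> np.ndarray:
        """Realized per-stratum coefficients B_{s,p} = mu_beta_p + w_{s,p}."""
        return self.mu_beta[None, :] + self.W

    def in_support(self, bounds: "PhiBounds") -> bool:
        return (
            self.sigma_beta0 > 0
            and np.all(self.sigma_beta > 0)
            and np.all(self.tau > 0)
            and bounds.lower <= self.phi0 <= bounds.upper
            and bounds.lower <= self.phiB <= bounds.upper
        )


@dataclass(frozen=True)
class PhiBounds:
    """Support of the uniform priors on the spatial decay parameters, 1/km."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError("phi bounds must satisfy 0 < lower < upper")


def phi_prior_bounds(
    D: DistanceMatrix, c_low: float = 0.01, c_high: float = 0.90
) -> PhiBounds:
    """Uniform prior support for phi from the inter-stratum distance range.

    The bounds make the Gaussian kernel span a correlation of ``c_high`` at
    the largest inter-stratum distance (slowest decay admitted) down to
    ``c_low`` at the smallest (fastest decay admitted).
    """
    if not (0 < c_low < c_high < 1):
        raise ValueError("need 0 < c_low < c_high < 1")
    if D.n_strata < 2:
        raise ValueError("need at least two strata")
    off = D.offdiagonal()
    d_min, d_max = float(off.min()), float(off.max())
    if d_min <= 0:
        raise ValueError("coincident strata: smallest inter-stratum distance is 0")
    lower = np.sqrt(-np.log(c_high)) / d_max
    upper = np.sqrt(-np.log(c_low)) / d_min
    return PhiBounds(lower=lower, upper=upper)


def linear_predictor(params: SVCParameters, panel: DesignPanel) -> np.ndarray:
    """Log-scale expected pond abundance mu_{s,t}, (S, Y-1)."""
    S, P = params.W.shape
    if panel.n_strata != S or panel.n_predictors != P:
        raise ValueError(
            f"parameter dimensions (S={S}, P={P}) do not match panel "
            f"(S={panel.n_strata}, P={panel.n_predictors})"
        )
    # Column 0 of X is the intercept, so folding (mu0 + w0) into the
    # coefficient matrix reproduces the intercept + offset form exactly.
    B_full = np.concatenate(
        [(params.mu0 + params.w0)[:, None], params.coefficient_field()], axis=1
    )
    return np.einsum("stp,sp->st", panel.X, B_full) + panel.offset[:, None]


def observation_loglik(
    panel: DesignPanel, mu: np.ndarray, tau: np.ndarray
) -> float:
    """Lognormal log-likelihood summed over modeled stratum-year cells.

    Includes the 1/pond Jacobian of the lognormal density, so this is the
    density of the counts themselves, not of their logs.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be strictly positive")
    y = panel.log_ponds_modeled
    if mu.shape != y.shape:
        raise ValueError("mu must match the modeled panel shape")
    z = (y - mu) / tau[:, None]
    per_cell = (
        -np.log(tau)[:, None] - 0.5 * _LOG_2PI - 0.5 * z**2 - y
    )
    return float(per_cell.sum())


def _gamma_logpdf(x: np.ndarray | float) -> np.ndarray | float:
    return gamma_dist.logpdf(x, GAMMA_SHAPE, scale=1.0 / GAMMA_RATE)


def _normal_logpdf(x: np.ndarray | float, sd: float) -> np.ndarray | float:
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * (np.asarray(x) / sd) ** 2


def log_prior(
    params: SVCParameters,
    bounds: PhiBounds,
    D: DistanceMatrix | None = None,
    include_fields: bool = True,
) -> float:
    """Joint log-prior of all unknowns.

    Covers the Normal(0, 10) means, Gamma(1.2, 0.2) scales, LKJ(1)
    correlation, uniform phi priors and — when ``include_fields`` (the
    default) and ``D`` is given — the MVN/matrix-normal densities of the
    spatial effect fields themselves.  Out-of-support parameters yield
    ``-inf``.
    """
    if not params.in_support(bounds):
        return -np.inf
    lp = float(_normal_logpdf(params.mu0, MU_PRIOR_SD))
    lp += float(np.sum(_normal_logpdf(params.mu_beta, MU_PRIOR_SD)))
    lp += float(_gamma_logpdf(params.sigma_beta0))
    lp += float(np.sum(_gamma_logpdf(params.sigma_beta)))
    lp += float(np.sum(_gamma_logpdf(params.tau)))
    lp += lkj_logpdf(params.rho, eta=1.0)
    span = bounds.upper - bounds.lower
    lp += -2.0 * np.log(span)  # uniform densities for phi0 and phiB
    if include_fields:
        if D is None:
            raise ValueError("distance matrix required for the field priors")
        lp += _field_log_prior(params, D)
    return lp


def _field_log_prior(params: SVCParameters, D: DistanceMatrix) -> float:
    """MVN term for w0 (intercept field) + matrix-normal term for W."""
    K0 = gaussian_correlation(params.phi0, D)
    L0 = cholesky_with_jitter(K0, "K0")
    S = params.n_strata
    z = solve_triangular(L0, params.w0, lower=True) / params.sigma_beta0
    logdet = 2.0 * float(np.sum(np.log(np.diag(L0)))) + 2.0 * S * np.log(
        params.sigma_beta0
    )
    lp = -0.5 * (S * _LOG_2PI + logdet + float(z @ z))
    KB = gaussian_correlation(params.phiB, D)
    T = build_T(params.sigma_beta, params.rho)
    lp += matrix_normal_logpdf(params.W, KB, T)
    return lp


def log_posterior_parts(
    params: SVCParameters,
    panel: DesignPanel,
    D: DistanceMatrix,
    bounds: PhiBounds | None = None,
) -> dict[str, float]:
    """The four addends of the joint log-posterior, by name.

    Keys: ``hyper_prior`` (means, scales, rho, phi), ``intercept_field``
    (MVN of w0), ``coefficient_field`` (matrix normal of W) and
    ``loglik`` (lognormal observation term).
    """
    if bounds is None:
        bounds = phi_prior_bounds(D)
    hyper = log_prior(params, bounds, include_fields=False)
    if not np.isfinite(hyper):
        return {
            "hyper_prior": hyper,
            "intercept_field": -np.inf,
            "coefficient_field": -np.inf,
            "loglik": -np.inf,
        }
    K0 = gaussian_correlation(params.phi0, D)
    w0_term = _mvn_logpdf(params.w0, params.sigma_beta0**2 * K0)
    KB = gaussian_correlation(params.phiB, D)
    T = build_T(params.sigma_beta, params.rho)
    W_term = matrix_normal_logpdf(params.W, KB, T)
    mu = linear_predictor(params, panel)
    ll = observation_loglik(panel, mu, params.tau)
    return {
        "hyper_prior": hyper,
        "intercept_field": w0_term,
        "coefficient_field": W_term,
        "loglik": ll,
    }


def _mvn_logpdf(x: np.ndarray, cov: np.ndarray) -> float:
    L = cholesky_with_jitter(cov, "covariance")
    z = solve_triangular(L, x, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (x.size * _LOG_2PI + logdet + float(z @ z))


def log_posterior(
    params: SVCParameters,
    panel: DesignPanel,
    D: DistanceMatrix,
    bounds: PhiBounds | None = None,
) -> float:
    """Joint log-posterior up to a constant; ``-inf`` outside the support."""
    parts = log_posterior_parts(params, panel, D, bounds)
    if not np.isfinite(parts["hyper_prior"]):
        return -np.inf
    return sum(parts.values())


def noncentered_effects(
    z0: np.ndarray,
    Z: np.ndarray,
    sigma_beta0: float,
    sigma_beta: np.ndarray,
    rho: np.ndarray,
    phi0: float,
    phiB: float,
    D: DistanceMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Map standard-normal innovations to the centered effect fields.

    ``w0 = sigma_beta0 * L_{K0} z0`` and ``W = L_{KB} Z L_T'`` with
    ``L_T = diag(sigma_beta) chol(rho)``, so standard-normal ``z0``/``Z``
    induce exactly the MVN/matrix-normal field priors.  The log-posterior
    evaluated at the mapped fields differs from the standard-normal density
    of the innovations only by a term constant in (z0, Z), which is what
    makes the two parameterizations interchangeable.
    """
    K0 = gaussian_correlation(phi0, D)
    L0 = cholesky_with_jitter(K0, "K0")
    w0 = sigma_beta0 * (L0 @ np.asarray(z0, dtype=float))
    KB = gaussian_correlation(phiB, D)
    LB = cholesky_with_jitter(KB, "KB")
    Lrho = cholesky_with_jitter(np.asarray(rho, dtype=float), "rho")
    LT = np.asarray(sigma_beta, dtype=float)[:, None] * Lrho
    W = LB @ np.asarray(Z, dtype=float) @ LT.T
    return w0, W
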