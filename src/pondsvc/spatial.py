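"""Spatial correlation kernels and separable covariance machinery.

The coefficient fields of the pond-abundance model are governed by an
isotropic Gaussian correlation kernel over inter-stratum distance and, for
the climate coefficients, by a separable (matrix-normal) covariance: a
spatial correlation matrix ``K`` among strata crossed with a
variance-covariance matrix ``T`` among predictors.  The matrix normal on an
S x P field is identical to a multivariate normal on the vectorized field
with covariance ``K (x) T`` (Kronecker product); that equivalence is the
central numerical contract of this module and is enforced by the test
suite.

All scale lives in ``T``: ``K`` is constrained to be a correlation matrix
(unit diagonal), which resolves the ``c*K, T/c`` non-identifiability of the
Kronecker factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import betaln

__all__ = [
    "NumericalError",
    "DistanceMatrix",
    "KernelParams",
    "CoefficientCovariance",
    "gaussian_correlation",
    "build_T",
    "matrix_normal_logpdf",
    "lkj_logpdf",
    "lkj_log_normalizer",
    "cholesky_with_jitter",
    "cpc_to_correlation",
    "sample_lkj",
]

_LOG_2PI = np.log(2.0 * np.pi)

#: Escalating diagonal jitter tried before giving up on a Cholesky
#: factorization.  Gaussian kernels at small phi are near-singular.
JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6)


class NumericalError(RuntimeError):
    """Linear-algebra failure that survived the jitter ladder."""


def cholesky_with_jitter(a: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Lower Cholesky factor of ``a``, adding diagonal jitter if needed.

    Jitter escalates through :data:`JITTER_LADDER`; beyond that a
    :class:`NumericalError` is raised with a condition-number report.
    """
    a = np.asarray(a, dtype=float)
    for jitter in JITTER_LADDER:
        try:
            return np.linalg.cholesky(
                a if jitter == 0.0 else a + jitter * np.eye(a.shape[0])
            )
        except np.linalg.LinAlgError:
            continue
    cond = np.linalg.cond(a)
    raise NumericalError(
        f"Cholesky of {name} failed after jitter up to {JITTER_LADDER[-1]:g} "
        f"(condition number {cond:.3e})"
    )


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise Euclidean distances among stratum centroids, in km."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(entries)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(entries < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.diag(entries) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(entries, entries.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n_strata(self) -> int:
        return self.entries.shape[0]

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_strata, k=1)
        return self.entries[iu]


@dataclass(frozen=True)
class KernelParams:
    """Spatial decay parameter of the Gaussian kernel, in 1/km."""

    phi: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("phi must be positive")


def gaussian_correlation(phi: float, D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Isotropic Gaussian correlation ``exp(-phi^2 * d^2)``.

    Parameters
    ----------
    phi
        Spatial decay, 1/km; must be positive.
    D
        Distance matrix (km) or a scalar/array of distances.
    """
    if not np.isscalar(phi) or not phi > 0:
        raise ValueError("phi must be a positive scalar")
    d = D.entries if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim == 2:
        if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix must be square and symmetric")
    return np.exp(-(phi**2) * d**2)


@dataclass(frozen=True)
class CoefficientCovariance:
    """Among-predictor covariance ``T = diag(sigma) rho diag(sigma)``."""

    sigma_beta: np.ndarray
    rho: np.ndarray
    T: np.ndarray

    @property
    def n_predictors(self) -> int:
        return self.T.shape[0]


def _validate_correlation(rho: np.ndarray, require_pd: bool = True) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(rho), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if require_pd:
        eigmin = np.linalg.eigvalsh(rho)[0]
        if eigmin <= 0:
            raise ValueError(
                f"correlation matrix is not positive definite (min eig {eigmin:.3e})"
            )
    return rho


def build_T(sigma_beta: np.ndarray, rho: np.ndarray) -> CoefficientCovariance:
    """Assemble the among-predictor covariance from sds and a correlation.

    The per-predictor sds ``sigma_beta`` and the correlation ``rho`` are
    modelled independently; their product defines the column covariance of
    the coefficient field.
    """
    sigma_beta = np.asarray(sigma_beta, dtype=float)
    if sigma_beta.ndim != 1 or np.any(sigma_beta <= 0):
        raise ValueError("sigma_beta must be a vector of positive reals")
    rho = _validate_correlation(rho)
    if rho.shape[0] != sigma_beta.size:
        raise ValueError("sigma_beta and rho dimensions disagree")
    T = sigma_beta[:, None] * rho * sigma_beta[None, :]
    return CoefficientCovariance(sigma_beta=sigma_beta, rho=rho, T=T)


def matrix_normal_logpdf(
    W: np.ndarray,
    K: np.ndarray,
    T: CoefficientCovariance | np.ndarray,
) -> float:
    """Log-density of a zero-mean matrix normal MN(0, K, T).

    ``K`` is the S x S row (spatial) covariance and ``T`` the P x P column
    (among-predictor) covariance.  Equals the multivariate-normal
    log-density of ``vec(W)`` under covariance ``K (x) T``.
    """
    W = np.asarray(W, dtype=float)
    K = np.asarray(K, dtype=float)
    Tm = T.T if isinstance(T, CoefficientCovariance) else np.asarray(T, dtype=float)
    S, P = W.shape
    if K.shape != (S, S) or Tm.shape != (P, P):
        raise ValueError("K/T shapes do not conform with W")
    Lk = cholesky_with_jitter(K, "K")
    Lt = cholesky_with_jitter(Tm, "T")
    # tr(T^-1 W' K^-1 W) = || Lt^-1 (Lk^-1 W)' ||_F^2
    A = solve_triangular(Lk, W, lower=True)
    B = solve_triangular(Lt, A.T, lower=True)
    quad = float(np.sum(B * B))
    logdet_K = 2.0 * float(np.sum(np.log(np.diag(Lk))))
    logdet_T = 2.0 * float(np.sum(np.log(np.diag(Lt))))
    return -0.5 * (S * P * _LOG_2PI + P * logdet_K + S * logdet_T + quad)


def lkj_log_normalizer(d: int, eta: float) -> float:
    """Log normalizing constant of the LKJ(eta) density on d x d correlations.

    Derived from the C-vine factorization in which the canonical partial
    correlations at tree level k are independent Beta(b_k, b_k) on (-1, 1)
    with b_k = eta + (d - 1 - k)/2.
    """
    if d < 2:
        return 0.0
    total = 0.0
    for k in range(1, d):
        b = eta + 0.5 * (d - 1 - k)
        total += (d - k) * ((2.0 * b - 1.0) * np.log(2.0) + betaln(b, b))
    return -total


def lkj_logpdf(rho: np.ndarray, eta: float = 1.0) -> float:
    """LKJ log-density of a correlation matrix; flat over the space at eta=1."""
    if not eta > 0:
        raise ValueError("eta must be positive")
    rho = _validate_correlation(rho)
    d = rho.shape[0]
    sign, logdet = np.linalg.slogdet(rho)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    return lkj_log_normalizer(d, eta) + (eta - 1.0) * logdet


def cpc_to_correlation(cpc: np.ndarray) -> np.ndarray:
    """Map C-vine canonical partial correlations to a full correlation matrix.

    ``cpc`` is a strictly-upper-triangular matrix whose (k, j) entry is the
    partial correlation of variables k and j given 1..k-1.
    """
    cpc = np.asarray(cpc, dtype=float)
    d = cpc.shape[0]
    rho = np.eye(d)
    for k in range(d - 1):
        for j in range(k + 1, d):
            r = cpc[k, j]
            for l in range(k - 1, -1, -1):
                r = r * np.sqrt((1 - cpc[l, k] ** 2) * (1 - cpc[l, j] ** 2)) + (
                    cpc[l, k] * cpc[l, j]
                )
            rho[k, j] = rho[j, k] = r
    return rho


def sample_lkj(d: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from LKJ(eta) via the C-vine construction."""
    cpc = np.zeros((d, d))
    for k in range(d - 1):
        b = eta + 0.5 * (d - 2 - k)
        cpc[k, k + 1 :] = 2.0 * rng.beta(b, b, size=d - k - 1) - 1.0
    return cpc_to_correlation(cpc)
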