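"""Post-inference transforms: effective range, variance partition, density/CV.

All derived quantities are computed per posterior draw and then
summarized (median and central 95% interval) — never from posterior-median
parameters — so their intervals propagate every source of uncertainty in
the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import DesignPanel

__all__ = [
    "DerivedSummary",
    "effective_range",
    "variance_explained",
    "density_and_cv",
    "derive_over_posterior",
]


def effective_range(phi: float | np.ndarray, threshold: float = 0.05) -> float | np.ndarray:
    """Distance (km) at which the Gaussian kernel decays to ``threshold``.

    Solves exp(-phi^2 d^2) = threshold, i.e. d = sqrt(-ln threshold)/phi;
    the conventional summary of a spatial correlation function (the 0.05
    crossing) that is more interpretable than phi itself.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0):
        raise ValueError("phi must be positive")
    return np.sqrt(-np.log(threshold)) / phi


def variance_explained(
    B_s: np.ndarray, X_s: np.ndarray, tau_s: float
) -> np.ndarray:
    """Per-predictor fractions of within-stratum pond variance.

    ``B_s`` are the stratum's realized (non-intercept) coefficients and
    ``X_s`` the (years x predictors) series of those covariates in the
    stratum; the fraction for predictor p is

        B_p^2 Var(x_p) / (sum_k B_k^2 Var(x_k) + tau_s^2),

    where Var is the sample variance over the modeled years — the
    empirical variability of the driver during the study period.  The
    residual lognormal variance tau_s^2 completes the partition.  A
    zero-variance predictor contributes 0.
    """
    B_s = np.atleast_1d(np.asarray(B_s, dtype=float))
    X_s = np.asarray(X_s, dtype=float)
    if X_s.ndim != 2 or X_s.shape[1] != B_s.size:
        raise ValueError("X_s must be (years, predictors) matching B_s")
    if X_s.shape[0] < 2:
        raise ValueError("need at least 2 modeled years for a sample variance")
    v = X_s.var(axis=0, ddof=1)
    contrib = B_s**2 * v
    denom = contrib.sum() + float(tau_s) ** 2
    if denom == 0:
        return np.zeros_like(contrib)
    return contrib / denom


def density_and_cv(
    beta0_s: float | np.ndarray,
    tau_s: float | np.ndarray,
    area_s: float | None = None,
    squared_cv: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratum mean pond density (ponds/km^2) and coefficient of variation.

    ``beta0_s`` is the offset-free stratum intercept (mu0 + w0_s), which
    the log-area offset places on the per-km^2 scale, so the lognormal
    mean density is exp(beta0 + tau^2/2).  The CV defaults to the standard
    lognormal form sqrt(exp(tau^2) - 1); ``squared_cv=True`` returns the
    un-rooted variant exp(tau^2) - 1 for figure-replication parity.
    ``area_s`` is accepted for converting density to an expected stratum
    total (density * area) by callers; it does not affect the density.
    """
    tau_arr = np.asarray(tau_s, dtype=float)
    if np.any(tau_arr <= 0):
        raise ValueError("tau must be strictly positive")
    density = np.exp(np.asarray(beta0_s, dtype=float) + 0.5 * tau_arr**2)
    cv = np.exp(tau_arr**2) - 1.0
    if not squared_cv:
        cv = np.sqrt(cv)
    return density, cv


@dataclass(frozen=True)
class DerivedSummary:
    """Posterior summaries of the derived ecological quantities.

    ``ranges``: effective ranges (km) of the intercept and coefficient
    kernels.  ``proportions``: per stratum x predictor variance fractions
    (plus the residual fraction, so each stratum partition sums to 1).
    ``density_cv``: per-stratum mean density and CV.
    """

    ranges: pd.DataFrame
    proportions: pd.DataFrame
    density_cv: pd.DataFrame


def _summary_row(vals: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.quantile(vals, [0.025, 0.5, 0.975], method="linear")
    return med, lo, hi


def derive_over_posterior(
    draws: PosteriorDraws, panel: DesignPanel
) -> DerivedSummary:
    """Compute every derived quantity per draw, then summarize.

    Requires the fitted panel for the empirical covariate variances and
    the stratum labels.
    """
    preds = panel.predictor_names[1:]
    strata = [n[len("w0[") : -1] for n in draws.names_matching("w0[")]
    S, P = len(strata), len(preds)
    pooled = draws.draws.reshape(-1, draws.draws.shape[2])
    col = {n: pooled[:, i] for i, n in enumerate(draws.parameter_names)}
    n_draws = pooled.shape[0]

    ranges_rows = []
    for label, pname in (("intercept", "phi0"), ("coefficients", "phiB")):
        rng_draws = effective_range(col[pname])
        med, lo, hi = _summary_row(rng_draws)
        ranges_rows.append(
            {"field": label, "median_km": med, "ci_lo": lo, "ci_hi": hi}
        )
    ranges = pd.DataFrame(ranges_rows)

    # variance partition, per draw and stratum
    xvar = panel.X[:, :, 1:].var(axis=1, ddof=1)  # (S, P)
    prop_draws = np.empty((n_draws, S, P + 1))
    tau_cols = np.column_stack([col[f"tau[{s}]"] for s in strata])  # (n, S)
    B = np.empty((n_draws, S, P))
    for j, p in enumerate(preds):
        mb = col[f"mu_beta[{p}]"]
        for i, s in enumerate(strata):
            B[:, i, j] = mb + col[f"w[{s},{p}]"]
    contrib = B**2 * xvar[None, :, :]
    denom = contrib.sum(axis=2) + tau_cols**2  # (n, S)
    prop_draws[:, :, :P] = contrib / denom[:, :, None]
    prop_draws[:, :, P] = tau_cols**2 / denom
    prop_rows = []
    for i, s in enumerate(strata):
        for j, p in enumerate(preds + ["residual"]):
            med, lo, hi = _summary_row(prop_draws[:, i, j])
            prop_rows.append(
                {
                    "stratum": s,
                    "predictor": p,
                    "proportion_median": med,
                    "ci_lo": lo,
                    "ci_hi": hi,
                }
            )
    proportions = pd.DataFrame(prop_rows)

    dens_rows = []
    for i, s in enumerate(strata):
        beta0 = col["mu0"] + col[f"w0[{s}]"]
        dens, cv = density_and_cv(beta0, tau_cols[:, i])
        dmed, dlo, dhi = _summary_row(dens)
        cmed, clo, chi_ = _summary_row(cv)
        dens_rows.append(
            {
                "stratum": s,
                "density_median": dmed,
                "density_ci_lo": dlo,
                "density_ci_hi": dhi,
                "cv_median": cmed,
                "cv_ci_lo": clo,
                "cv_ci_hi": chi_,
            }
        )
    density_cv = pd.DataFrame(dens_rows)
    return DerivedSummary(
        ranges=ranges, proportions=proportions, density_cv=density_cv
    )
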