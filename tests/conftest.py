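import numpy as np
import pytest

import pondsvc as p


@pytest.fixture(scope="session")
def study12():
    """A 12-stratum, 30-year synthetic study with the default truth."""
    geometry, climate, truth = p.simulate_study(12, 30, seed=7)
    return geometry, climate, truth


@pytest.fixture(scope="session")
def geometry8():
    return p.make_geometry(8, seed=42)


@pytest.fixture(scope="session")
def fitted_small():
    """A short fit on a small study, shared by summary/derive tests."""
    geometry, climate, truth = p.simulate_study(6, 14, seed=11)
    draws = p.run_mcmc(
        truth.panel, geometry, chains=2, warmup=100, kept=150, seed=19
    )
    return geometry, truth, draws


def exogenous_panel(geometry, n_modeled_years, n_predictors, seed):
    """A DesignPanel with exogenous standard-normal covariates (no lag).

    Used by tests that need a linear-Gaussian panel free of the
    autoregressive feedback; pond counts are exp of the response so the
    lognormal panel contract still holds.
    """
    rng = np.random.default_rng(seed)
    S, T = geometry.n_strata, n_modeled_years
    Z = rng.standard_normal((S, T, n_predictors))
    X = np.concatenate([np.ones((S, T, 1)), Z], axis=2)
    y = rng.standard_normal((S, T))
    ponds = np.empty((S, T + 1))
    ponds[:, 0] = 1.0
    ponds[:, 1:] = np.exp(y)
    names = ["intercept"] + [f"x{i + 1}" for i in range(n_predictors)]
    return p.DesignPanel(
        ponds=ponds,
        X=X,
        offset=geometry.offset,
        years=np.arange(T + 1),
        predictor_names=names,
    )
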