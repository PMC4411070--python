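# pondsvc

Bayesian **spatially varying coefficient (SVC)** modelling of annual
spring pond abundance in the Prairie Pothole and Great Plains regions of
North America.

Wetland ("pond") counts from a stratified aerial survey are strongly
driven by the previous year's water conditions and by seasonal climate —
but not uniformly in space: the drivers in Montana are not the drivers in
Manitoba.  Conventional regressions fit a single coefficient per driver
and so report an average that may hold nowhere.  `pondsvc` instead treats
every coefficient as a spatial field and quantifies, stratum by stratum,
how much of the year-to-year variance each driver explains.

This package is aimed at quantitative ecologists and biostatisticians who
want a fully tested, reproducible implementation of the model — from
covariate construction through MCMC to derived ecological summaries —
exercised end-to-end on synthetic data that emulates the survey's panel
structure.

## The model

Counts are lognormal with stratum-specific dispersion,

    Pond_{s,t} ~ LN(mu_{s,t}, tau_s)
    mu_{s,t}  = (mu_0 + w0_s) + sum_p (mu_beta_p + w_{s,p}) x_{s,t,p} + log(area_s)

with predictors: log lagged count, a linear time trend, and log total
precipitation and mean daily-maximum temperature for the four seasons
preceding the survey.  The intercept deviations follow a Gaussian-kernel
multivariate normal, `w0 ~ MVN(0, sigma_b0^2 K_0(phi_0))`, and the
coefficient deviations a **separable matrix normal**,
`W ~ MN(0, K_B(phi_B), T)` with `T = diag(sigma_b) rho diag(sigma_b)` —
equivalently `vec(W) ~ MVN(0, K_B ⊗ T)`.  Priors: N(0, 10) on means,
Gamma(1.2, 0.2) on all sds, LKJ(1) on `rho`, and uniform priors on the
kernel decays spanning correlation 0.90 at the largest inter-stratum
distance to 0.01 at the smallest.

Inference is a partially collapsed blocked Gibbs sampler (exact joint
Gaussian draws for all means and fields; kernel and scale parameters
updated with their fields integrated out; slice sampling for the rest)
that targets the exact posterior — see `docs/methods.md` for the design
and its validation (conjugate oracles, prior recovery, simulation-based
calibration).

## Worked example

```python
import numpy as np
import pondsvc as p

# a synthetic 12-stratum, 30-year study with empirically calibrated truth
geometry, climate, truth = p.simulate_study(12, 30, seed=7)
draws = p.run_mcmc(truth.panel, geometry, chains=2, warmup=300, kept=600, seed=8)
table = p.posterior_summary(draws, truth.panel).set_index("parameter")

beta_true = truth.params.mu_beta[0] + truth.params.W[0, 0]
row = table.loc["beta[S01,log_lag]"]
print(f"stratum S01 lag coefficient: {row['median']:.3f} "
      f"({row.ci_lo:.3f}-{row.ci_hi:.3f})  truth {beta_true:.3f}")
mu_row = table.loc["mu_beta[log_lag]"]
print(f"global lag mean:             {mu_row['median']:.3f} "
      f"({mu_row.ci_lo:.3f}-{mu_row.ci_hi:.3f})  truth {truth.params.mu_beta[0]:.3f}")
print("max split-Rhat:", round(draws.diagnostics["max_split_rhat"], 3))

derived = p.derive_over_posterior(draws, truth.panel)
print(derived.ranges.to_string(index=False))
props = derived.proportions.query("stratum == 'S01' and predictor != 'residual'")
top = props.nlargest(3, "proportion_median")[["predictor", "proportion_median"]]
print(top.to_string(index=False))
```

Output from this exact script:

```
stratum S01 lag coefficient: 0.227 (0.134-0.316)  truth 0.269
global lag mean:             0.450 (-1.942-4.911)  truth 0.259
max split-Rhat: 1.326
       field   median_km      ci_lo       ci_hi
   intercept  506.226384 228.067365 2098.120888
coefficients 7481.902832 627.533089 8999.236816
        predictor  proportion_median
          log_lag           0.315264
log_precip_summer           0.167650
  log_precip_fall           0.037172
```

The quantities ecology cares about are well recovered: the *realized*
stratum-level lag coefficient (0.227, interval 0.134-0.316) sits on its
generating value 0.269, and the variance partition correctly names the
lag and summer precipitation as stratum S01's dominant drivers.  The
*global* lag mean is honestly wide: with only 12 strata the posterior
keeps mass on a slow-decay regime (coefficient effective range running
to the prior ceiling near 9000 km) in which a near-common lag field and
the global mean trade off — an identification ridge the real survey's
24 strata x 51 years suppresses (there the reported ranges are
688 and 644 km).  The max split-Rhat of 1.33 at this deliberately short
chain length sits in the gate's "fail" band; the pipeline's `fit`
command would demand longer chains (the survey-scale default is
5 chains x (400 + 2000)).

A command-line pipeline wraps the same stages:

```bash
pondsvc simulate     --outdir run --n-strata 12 --n-years 30 --seed 1
pondsvc build-design --outdir run
pondsvc fit          --outdir run --chains 5 --warmup 400 --kept 2000 --seed 1
pondsvc derive       --outdir run
pondsvc report       --outdir run
```

`fit` enforces a convergence gate on the maximum split-Rhat
(pass <= 1.05, warn <= 1.10, else nonzero exit) and every stage writes a
JSON manifest (seed, config hash, diagnostics) sufficient to reproduce
it bit-exactly.

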