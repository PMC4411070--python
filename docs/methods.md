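# Methods

## The model

`pondsvc` models visibility-corrected May pond counts from a stratified
aerial survey of the Prairie Pothole and Great Plains regions.  Counts are
strictly positive, right-skewed and heteroscedastic across strata, so the
observation model is lognormal:

    Pond_{s,t} ~ LogNormal(mu_{s,t}, tau_s),

with a stratum-specific log-scale dispersion `tau_s` and a linear
predictor

    mu_{s,t} = (mu_0 + w0_s)
             + sum_p (mu_beta_p + w_{s,p}) x_{s,t,p}
             + log(area_s).

The log-area offset puts the intercept on the density (ponds/km^2) scale.
Every coefficient is *spatially varying*: a global mean plus a
stratum-level deviation field.  The intercept deviations follow

    w0 ~ MVN(0, sigma_beta0^2 K_0(phi_0)),

and the deviations of the ten predictor coefficients follow a separable
matrix normal

    W ~ MN(0, K_B(phi_B), T),   T = diag(sigma_beta) rho diag(sigma_beta),

equivalent to `vec(W) ~ MVN(0, K_B (x) T)`.  Both kernels are isotropic
Gaussian, `K(d) = exp(-phi^2 d^2)`, on planar-km centroid distances.  The
intercept gets its own kernel because the geomorphology that created the
potholes need not share the spatial dependence of present-day climate
effects; the climate coefficients share one kernel but are allowed
arbitrary among-coefficient correlation `rho` — a compromise between
fully separable and fully nonseparable covariance.  `K` is constrained to
unit diagonal (a correlation matrix) with all scale in `T`, which resolves
the `cK, T/c` non-identifiability of the Kronecker factorization.

Predictors, in fixed order: log of the previous year's count (lag),
integer survey-year index (time), log total precipitation and mean
daily-maximum temperature for the four seasons preceding the survey
(summer, fall, winter, spring).  Covariates are deliberately left
unstandardized so coefficients stay on interpretable scales
(per log-mm, per degC, per year).

Priors: Normal(0, sd 10) on `mu_0` and each `mu_beta_p`; Gamma(shape 1.2,
rate 0.2) — mean 6, sd ~5.48 — on every standard deviation
(`sigma_beta0`, each `sigma_beta_p`, each `tau_s`); LKJ(eta=1), i.e.
uniform over valid correlation matrices, on `rho`; and independent
uniform priors on `phi_0`, `phi_B` whose support is derived from the
geometry: the slowest admissible decay leaves correlation 0.90 at the
largest inter-stratum distance, the fastest leaves 0.01 at the smallest.
The first survey year is used only as the lag source and is excluded from
the likelihood.

## Posterior computation

Inference is a **partially collapsed blocked Gibbs sampler**, designed
around three structural facts of this posterior:

1. *Joint Gaussian field block.*  Given scales and kernels,
   `(mu_0, mu_beta, w0, vec W)` is jointly Gaussian.  The global means
   and the field means are nearly unidentified separately (only their
   sums enter the likelihood), so they are drawn in one exact
   multivariate-normal block; updating them separately produces a
   random walk along the trade-off direction that effectively never
   converges.

2. *Collapsed kernel/scale updates.*  Each field's scale and decay
   parameters are updated with the field integrated out analytically —
   `(sigma_beta0, phi_0)` against the exact marginal of the per-stratum
   residual means, and `(sigma_beta, phi_B)` against the Woodbury form of
   the marginal likelihood through the capacitance matrix
   `C = (K_B (x) T)^{-1} + Z' D^{-1} Z` — then the field is redrawn from
   its full conditional.  Conditioning on a realized field traps chains
   in hyperparameter regimes (e.g. a degenerate small-`phi_B`,
   large-`sigma_lag` regime in which the lag field mimics a common
   intercept shift); the collapsed updates move freely between regimes
   and weight them correctly.  A diagonal-scaling identity
   (`S log|T| + log|C| = S log|rho| + log|G|` with `G` the sigma-scaled
   capacitance) keeps each evaluation to a single Cholesky.

3. *Slice-sampled scalars.*  Each `tau_s` and each free entry of `rho`
   uses Neal's stepping-out/shrinkage slice sampler on its exact
   conditional; `rho` entries see the flat LKJ(1) prior with positive
   definiteness enforced by a Cholesky feasibility check.  The free
   entries of `rho` are swept five times per scan — the entry-wise moves
   are cheap but coupled through the positive-definiteness constraint,
   and repeated sweeps markedly shorten the autocorrelation of the
   correlation matrix.

Every update targets the exact joint posterior, so the scheme samples
the same distribution a Hamiltonian Monte Carlo implementation would.
Correctness is verified three independent ways in the test suite:
analytic conjugate-regression oracles for the collapsed model,
prior-moment recovery with the likelihood masked, and simulation-based
calibration (uniformity of the rank of prior-drawn truths within
posterior draws).

Chain protocol defaults are 5 chains x (400 warmup + 2000 kept).
Initialization draws scales from the prior conditioned below its mean
(diffuse Gamma draws make the kernel systems ill-conditioned), means
from N(0,1), decays uniformly in their support, with up to 10 restarts.
Convergence is monitored with the classic split potential scale
reduction factor (each chain halved; between/within variance ratio over
the half-chains); constant identical chains are flagged NaN rather than
silently 1, diverged constant chains report +inf.  The pipeline gate is
max split-Rhat <= 1.05 pass, <= 1.10 warn, else fail with nonzero exit.

## Synthetic data generator

The generator emulates the survey's panel structure so the whole pipeline
is testable without the proprietary survey and interpolated-climate data:

- **Geometry**: jittered-grid centroids (35% jitter of the cell size) in
  a 1500 km square — roughly the Prairie extent — with lognormal areas
  around 8000 km^2.  24 strata at that extent give a mean
  nearest-neighbour distance of ~250-300 km, matching the survey's
  spacing.
- **Climate**: seasonal log-precipitation and temperature fields with an
  east-west wetness gradient and a north-south temperature gradient,
  plus spatially correlated annual anomalies (Gaussian kernel, default
  effective range ~495 km; log-precip sd 0.30, tmax sd 1.8 degC).
  Seasonal means (200/105/60/115 mm; 25.5/10.5/-5/11 degC) are typical
  midcontinent values.  Precipitation is generated on the log scale,
  hence strictly positive.
- **Truth**: hyperparameters are *fixed by configuration*, not drawn
  from the diffuse hyperpriors, so recovery experiments have a defined
  target.  The ten coefficient means and sds default to the posterior
  medians reported for this system (lag 0.259/0.144, seasonal
  precipitation 0.343/0.206, 0.251/0.182, 0.372/0.189, 0.315/0.112,
  seasonal temperature -0.020/0.024, -0.017/0.036, -0.010/0.011,
  -0.039/0.033, time 0.004/0.007), so synthetic panels exercise the
  model in its empirically relevant regime.  The global intercept is
  instead calibrated: propagating a large reported intercept and
  intercept sd through the lag recursion together with the synthetic
  climate would imply pond densities spanning many orders of magnitude,
  so `mu_0 = -7.26` is chosen to put the stationary density near
  1 pond/km^2 under the default climate, and `sigma_beta0 = 1.5` gives
  a moderate (factor ~e^3) between-stratum density spread.  Stratum
  dispersions `tau_s` are lognormal around 0.25.  Kernel decays default
  to effective ranges of 688 km (intercept) and 644 km (coefficients).
- **Ponds**: simulated sequentially; year t's design row is built from
  year t-1's realized count and year t's climate, and the count drawn
  lognormally.  A total lag coefficient of magnitude >= 1 in any stratum
  triggers a non-stationarity warning rather than an error.

What the generator does *not* emulate: gridded sub-stratum climate
variation, multi-year wet-drought regime cycling, survey measurement
protocol changes, or wetland-type heterogeneity.  Passing recovery tests
therefore demonstrate statistical correctness of the estimator under the
model's own assumptions, not robustness to the real data's violations of
them.

## Covariate construction

Monthly station-interpolated climate enters as (stratum, calendar year,
month, precipitation, daily-max temperature) records.  Seasonal windows
are anchored to the late-May survey of year t: summer = Jun-Aug (t-1),
fall = Sep-Nov (t-1), winter = Dec (t-1) + Jan-Feb (t), spring = Mar-May
(t), the survey-year spring window taken whole.  Precipitation is summed
within the window and logged per season; temperature is the unweighted
mean of monthly means.  Zero seasonal precipitation totals are treated as
upstream data failures and rejected loudly — no silent +1 offsets.

## Derived quantities

All derived quantities are computed per posterior draw and then
summarized (median, central 95% interval by linear interpolation of
order statistics) — never from posterior-median parameters.

- **Effective range**: the distance at which the kernel decays to 0.05,
  `d = sqrt(-ln 0.05)/phi`.  The square root is required for dimensional
  consistency with the Gaussian kernel, so that the kernel genuinely
  equals 0.05 at the reported distance (verified to 1e-12 by round-trip
  tests).
- **Variance partition**: for stratum s the fraction of within-stratum
  variance attributed to predictor p is
  `B_{s,p}^2 Var(x_{s,.,p}) / (sum_k B_{s,k}^2 Var(x_{s,.,k}) + tau_s^2)`,
  with `Var` the sample variance of the realized covariate series over
  the modeled years and a single residual term `tau_s^2` — `tau` carries
  no predictor index anywhere in the model, so the residual enters the
  denominator once.  Fractions plus the residual share partition unity
  exactly, per stratum and per draw.  Zero-variance predictors (e.g. a
  constant column) contribute exactly 0.
- **Density and CV**: mean density `exp(beta0_s + tau_s^2/2)` per km^2
  (the offset-free intercept is already on the density scale) and the
  standard lognormal coefficient of variation
  `sqrt(exp(tau_s^2) - 1)`; the squared variant `exp(tau_s^2) - 1` is
  available behind `squared_cv=True` for parity with figure conventions
  that print the un-rooted form.  `tau_s` is the only per-stratum
  dispersion in the model and is the sigma used in both transforms.

## Numerical choices

- Cholesky factorizations of kernel matrices use an escalating diagonal
  jitter ladder (0, 1e-10, 1e-8, 1e-6); failures beyond that raise with
  a condition-number report.  Gaussian kernels near the lower phi bound
  are close to singular by construction.
- The LKJ normalizing constant follows from the C-vine factorization,
  `log c_d(eta) = -sum_k (d-k) [(2 b_k - 1) ln 2 + ln B(b_k, b_k)]`,
  `b_k = eta + (d-1-k)/2`; cross-checked against the closed-form d=2
  density (1/2) and the volume of the 3x3 elliptope (pi^2/2).
- Posterior summaries pool chains and use numpy's linear quantile
  interpolation; the rule is recorded in the output metadata.
- Test and acceptance runs use reduced problem sizes chosen to keep the
  whole suite desk-scale: recovery at 12 strata x 30 years with
  2 chains x (200 + 200), simulation-based calibration at 8 strata x
  20 years x 3 predictors with 63 replicates, the command-line smoke
  pipeline at 8 strata x 18 years with 2 chains x (300 + 700).

## Known limitations

- At small stratum counts the global coefficient means sit on an
  identification ridge with their fields: when the posterior visits
  decays near the lower `phi` bound the coefficient field is close to a
  common shift, exchangeable with the global mean, so e.g.
  `mu_beta[log_lag]` carries a wide honest interval while the realized
  per-stratum coefficients `beta[s, log_lag]` stay tight.  The summaries
  ecology uses (stratum coefficients, variance partitions) are the
  well-identified ones; survey-scale panels (24 strata, 51 years)
  identify the decays away from the bound and suppress the ridge.
- The entry-wise `rho` updates, though repeated, remain the slowest
  mixing component; short chains can leave split-Rhat for individual
  correlations in the 1.05-1.1 band.  The correlations are also the
  least-identified parameters at survey scale (the posterior is close
  to the LKJ prior), so their slow mixing barely affects the
  coefficient and variance-partition summaries.
- With few strata the kernel decays are weakly identified and their
  posteriors lean on the uniform prior bounds; effective-range intervals
  should be read accordingly.
- The sampler's joint field block scales as O((S P)^3) per iteration,
  comfortable for survey-scale problems (S ~ 24, P ~ 10) but not
  intended for hundreds of spatial units.
- Counts are treated as exact; the upstream visibility correction's
  sampling error is not propagated.
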