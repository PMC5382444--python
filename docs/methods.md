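# Methods

## The problem

Short-term exposure to ground-level ozone is an established trigger of
pediatric respiratory emergency-department (ED) visits.  Whether the
neighborhood socioeconomic environment modifies that association is harder to
establish: single-city analyses are underpowered and inconsistent across SES
indicators.  This package implements a two-stage design for multi-city,
small-area (ZCTA-level) analysis:

* **Stage 1** — within each ZCTA *z*, a time-stratified case-crossover
  analysis estimates the log odds ratio `beta_z` (per ppb of the 3-day
  moving-average 8-h max ozone) by conditional logistic regression, together
  with its variance `V_z`.
* **Stage 2** — the `(beta_z, V_z)` are pooled in a two-level normal Bayesian
  hierarchical meta-regression:

      beta_z  | theta_z, V_z      ~  N(theta_z, V_z)
      theta_z | alpha0, gamma, tau^2 ~ N(alpha0 + sum_j gamma_j X_zj, tau^2)

  where `X_zj` are ZCTA-level covariates (city indicators and SES measures),
  `alpha0` the average per-ppb log OR at the covariate reference, `gamma_j`
  the effect modification per unit of `X_j`, and `tau^2` the between-ZCTA
  heterogeneity unexplained by the covariates.

Because real ED line lists are confidential hospital records, a synthetic
three-city generator with recorded ground truth is a first-class component:
every pipeline stage is validated by parameter recovery against the
generator's own truth.

## Stage 1: case-crossover conditional logistic regression

**Referent selection.** For a visit on day *t*, referent days are all other
days in the same calendar month and year sharing *t*'s day of week (3 or 4
referents).  Matching on year/month/day-of-week removes long-term trend,
seasonal and weekday confounding by design; within-person time-invariant
confounders cancel because each visit is compared to itself.

**Likelihood.** With one case per matched set the conditional likelihood is
the softmax form `l(b) = sum_s [x_case.b − log sum_rows exp(x_row.b)]`.
Visits on the same date in the same ZCTA have identical matched sets, so they
are collapsed into one stratum with an integer weight; this is an exact
reformulation, not an approximation (verified by a dedicated test).

**Covariates.** Season (4 meteorological quarters), day-of-week, US federal
holidays, optional hospital-participation period indicators, cubic
polynomials of the 3-day moving-average maximum temperature and mean dew
point (city-level, one station per city), season × maximum-temperature
interactions, and a natural cubic spline on day of year with 5 df.  Day of
year uses a common 1–366 scale (Feb 29 = 60, later days shifted in non-leap
years) so the same date maps to the same value each year.  Spline knots sit
at the min/max and four equally spaced interior quantiles of observed day of
year.  Covariates constant within every stratum (day of week, season, a
full-period hospital indicator) provably cancel from the conditional
likelihood; they are retained in the design and dropped at estimation time
when their within-stratum-centered values are numerically zero (< 1e-10).

**Optimization.** Newton iterations on within-stratum-centered,
max-abs-equilibrated columns (equilibration is a linear reparametrization and
leaves the estimates unchanged; it protects the Hessian solve from the poor
conditioning of raw cubic temperature terms).  Convergence at gradient
max-norm < 1e-8 or 100 iterations, with step halving.  The variance is the
inverse observed information.  The reported ozone coefficient is per ppb;
scaling to 25 ppb happens only in reporting.

**Exclusions.** ZCTAs with fewer than 50 total visits over the study period
are excluded before fitting (sparse sets are numerically fragile and
contribute almost no information).  Case or referent days whose lag-0–2
exposure window is undefined (start of the study period, missing meteorology)
are removed from strata rather than imputed; a stratum reduced to its case
row alone is dropped and logged.

## Exposure and SES inputs

Ozone is supplied as a daily gridded field; each ZCTA's value is the
area-weighted average of its overlapping cells (weights = overlap areas
normalized to 1 per ZCTA).  The analysis exposure is the lag-0–2 moving
average, undefined for the first two study days.

SES values observed at two census waves are linearly interpolated to yearly
values (the 5-year survey wave is anchored at its midpoint year, the standard
convention for period estimates) and averaged over each city's study period.
The Neighborhood Deprivation Index (NDI) is the first principal component of
the correlation matrix of eight standardized deprivation indicators, computed
within each city, re-standardized to mean 0 / SD 1 and oriented so that
higher NDI means more deprivation (positive correlation with % below
poverty).  Categorical designations: undereducated area (% < 12th grade
>= 25), poverty area (% below poverty >= 20), and NDI strictly above its 90th
percentile (linear-interpolation quantile; pooled across cities by default,
per-city via an option, since either convention is defensible).

## Stage 2: the hierarchical fitter

The prior is flat on the coefficients and flat on `tau` over `[0, tau_max]`
with `tau_max` set to 10× the dispersion of the stage-1 estimates — wide
enough to be effectively noninformative while keeping a proper numerical
integral (a flat-on-`tau^2` alternative is exposed via `tau_prior="tau2"`).
For fixed `tau` the coefficient posterior is the GLS normal with weights
`1/(V_z + tau^2)`; the `tau` marginal is known up to a constant and is
integrated on a two-pass grid (201 coarse points, then 201 points refined
over the region within 15 log-units of the mode) with trapezoidal weights.
Reported means/SDs are the `tau`-mixture moments; everything is
deterministic.  Forcing the grid to `{0}` reproduces inverse-variance
weighted least squares exactly, which anchors the implementation to a
closed-form limit (tested to 1e-10), and the full mixture matches dense 2-D
brute-force quadrature on toy problems to 1e-4.

Design conventions: the overall combined model uses one indicator column per
city and no intercept (equivalent to an intercept plus two indicators);
effect-modification models use an intercept, indicators for the non-reference
cities, and the SES modifier — a 0/1 flag or raw polynomial columns
`x, x^2, x^3` of the untransformed percentage/NDI value (native-scale curves;
optional centering is a caller-side transformation).  Significance uses the
Wald rule |estimate/posterior SD| > 1.96 (strict).  ORs are reported per
25 ppb, `exp(25·x'g)`, with Wald-style 95% posterior intervals from the full
mixture covariance of the linear predictor; mixture quantile intervals would
also be defensible, but the Wald form matches the 1.96 significance
convention used throughout.

## The synthetic generator

Defaults reproduce the study layout: Atlanta 2002–2008 (191 ZCTAs), Dallas
2006–2008 (253), St. Louis 2002–2007 (256); `alpha0 = log(1.08)/25` per ppb
(OR 1.08 per 25 ppb at the SES reference), a linear poverty modifier of
2e-4 per % per ppb, `tau = 0.001`.

* **Exposure**: a small rectangular lattice per city; each cell's daily 8-h
  max ozone is a city mean (≈40–42 ppb) plus a smooth annual cycle peaking in
  mid-July (amplitude 12 ppb), citywide daily noise (SD 6 ppb) and cell-level
  noise (SD 2 ppb), clipped at 0.  ZCTAs overlap up to 4 neighboring cells
  with Dirichlet fractions, so area weighting is genuinely exercised.
* **Meteorology**: city-level sinusoidal maximum temperature (city means
  ≈58–69 °F, amplitude 18 °F) with dew point tracking it.
* **SES**: eight indicators loaded on a latent per-ZCTA deprivation factor
  with field-typical means/SDs (e.g. % poverty mean 13, SD 8), two waves
  correlated ≈0.9, clipped to [0, 100].
* **Truth**: `theta_z = alpha0 + gamma · X_z + N(0, tau^2)` where `X_z` is
  the period-averaged interpolated SES value the analysis itself computes, so
  recovery tests compare like with like.
* **Counts**: daily Poisson with log-rate `b_z + c·C(t) + theta_z·o3ma_z(t)`;
  the shared annual cycle `C(t)` enters both the ozone mean and the log-rate
  with confounding amplitude `c = 0.3`, so stage-1 covariate control is
  necessary, not decorative.  Baseline rates are log-uniform on
  (0.02, 1.5) visits/day, spanning sparse ZCTAs (exercising the 50-visit
  exclusion) up to busy ones, consistent with per-ZCTA totals from tens to
  thousands of visits.  The line list replicates each date count times —
  with independent visits, Poisson daily counts and individual Bernoulli
  visits are equivalent.

What the generator does **not** emulate: spatial autocorrelation of ozone
beyond the lattice, hospital catchment structure, within-person repeat
visits, day-of-week visit patterns, co-pollutants, and exposure measurement
error (the analysis sees the same fused field that generated the counts).
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features.

## Validation experiments and problem sizes

* End-to-end recovery: 3 cities × 150 ZCTAs × 3 years per replicate,
  50 replicates in the test suite (12 in the acceptance script); the
  replicate mean of the posterior means must sit within 2 Monte-Carlo SEs of
  truth for both `alpha0` and the poverty `gamma`, and 95% interval coverage
  of `alpha0` within binomial tolerance.  These sizes give Monte-Carlo SEs
  of roughly 7% of `alpha0` while completing in a few minutes.
* Type-I error: one 450-ZCTA study with each ZCTA's daily ozone permuted
  across dates; the 1.96 rule rejects in ≈5% of ZCTAs (3-SE binomial band).
  Richer baselines (0.3–1.5 visits/day) are used here so that per-ZCTA
  likelihoods are in the asymptotic regime where the Wald test is calibrated.
* Oracles: paired-binary closed form `log(7/3)`; dense grid-search MLE for
  continuous exposure; statsmodels' conditional logit as an independent
  cross-check; brute-force 2-D quadrature and the WLS limit for stage 2.

## Numerical choices and degenerate inputs

* Conditional logit: non-identifiable exposure (no within-stratum variation
  anywhere) raises an error; non-convergence flags the ZCTA rather than
  failing the city run.  Log-sum-exp is max-shifted.
* tau posterior mean is biased upward when the true `tau` is near 0 (the
  prior mass at small positive values dominates a nearly flat likelihood);
  this is a property of the estimand, not a defect, and coefficient
  inference remains calibrated (coverage test).
* `beta` of a zero-rate ZCTA day: a `-inf` baseline log-rate is an explicit
  sentinel producing zero counts.
* NDI requires ≥ 9 ZCTAs per city and errors on (numerically) constant
  indicators; scores are invariant to affine rescaling of any indicator.

## Limitations

Meteorology is city-level, so within-city meteorological gradients are
uncontrolled.  The hierarchical model assumes normal first-stage sampling
error and a common modifier effect across cities in combined models
(city-specific fits relax the latter).  Additive-scale interaction measures
(RERI, synergy index) are out of scope, as are the observation/model fusion
producing the gridded ozone field, polygon geometry (overlap areas are an
input), and cartographic rendering (per-ZCTA OR tables are exported for
joining to user geometry).
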