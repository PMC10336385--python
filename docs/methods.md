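# Methods

## The estimation problem

A subset of a gillnet fleet carries electronic monitoring (EM: GPS plus
cameras), giving a census of harbour-porpoise bycatch on the monitored
fishing days.  Logbooks and sales notes give fishing effort for the whole
fleet, but no bycatch.  The task is to raise the monitored bycatch rates to
the fleet, accounting for the fact that bycatch risk depends strongly on how,
where and when a net is fished — mesh size, soak time, net length, depth,
season, region — and that monitored vessels are not a random sample of the
fleet with respect to those characteristics.

The analysis unit throughout is one fishing day of one vessel in one ICES
statistical rectangle (1° longitude × 0.5° latitude).  Two estimators are
implemented and compared:

1. **Stratified raising** (`stratified`): mean bycatch per fishing day (BPUE)
   per quarter × ICES-area stratum from EM data, multiplied by fleet fishing
   days in the same strata; percentile confidence intervals from a
   non-parametric bootstrap resampling EM fishing-day rows within stratum
   (optionally blocking by vessel).  This is the classical comparator; it
   ignores operational covariates.
2. **Model-based prediction** (`glmm` + `predict`): a negative-binomial mixed
   model fitted to the EM fishing days, used to predict expected bycatch for
   every fleet fishing day, summed with bias correction.

## The mixed model

Counts per vessel-day-rectangle are NB2,

    y_i ~ NB(mu_i, theta),      Var(y_i) = mu_i + mu_i^2 / theta,
    log mu_i = x_i' beta + b_vessel(i) + b_year(i) + s_g(i)(r_i),

with treatment-coded fixed effects (mesh-size class, vessel-length class,
porpoise population, log net-length, log soak-time, log depth, and the
mesh-class × log-soak-time interaction; reference levels "<120 mm", "<8 m",
"North Sea Population"), iid Gaussian vessel and year intercepts, and a
zero-mean Gaussian spatial field per group g with exponential covariance

    Cov(s(r), s(r')) = sigma_s^2 exp(-d(r, r') / rho),

d the great-circle distance (km) between rectangle centroids.  The grouping
is configurable (none / year / quarter / quarter-within-year); fields are
independent across groups and share (sigma_s, rho).  NB2 is used because the
monitored counts are overdispersed relative to Poisson; the log link makes
covariate effects multiplicative on the bycatch rate.

### Laplace-approximated likelihood

Latent effects are standardized, u = L(phi) v with v ~ N(0, I) and L the
block Cholesky factor of Cov(u).  The marginal likelihood is approximated by
Laplace's method at the conditional mode v-hat (found by damped Newton
iterations; the conditional Hessian I + L'Z'WZL is positive definite because
the NB2 working weights are non-negative):

    log L ≈ loglik(y | L v-hat) - ||v-hat||^2 / 2 - log det(I + L'Z'WZL) / 2.

This parameterization is exact in two useful limits — it reduces to the plain
fixed-effects NB likelihood when all variance components are zero, and it is
exactly the closed-form marginal for a Gaussian response — both of which are
asserted by tests.  A mode-centred 1-D quadrature oracle bounds the
approximation error on a 20-observation random-intercept toy below 1e-3.

Each data row loads exactly one coordinate of each random component, so
Z'WZ restricted to the spatial coordinates is diagonal and the conditional
Hessian factorizes as one small dense block per spatial group plus a Schur
complement the size of the iid block; same-size groups go through batched
numpy Cholesky calls.

### Outer optimization and conditioning

The outer parameters (beta, log theta, log SDs, log rho) are maximized with
bounded L-BFGS-B using central finite-difference gradients (step 1e-5).
One-sided differences are not accurate enough: the surface has strongly
correlated, nearly flat directions and one-sided noise stalls the line
search far from the optimum.  For the same reason the fixed-effects columns
are rotated to an orthonormal basis (X → Q√n from a QR decomposition) before
fitting; raw treatment-coded designs with log covariates have condition
numbers that defeat a finite-difference quasi-Newton loop.  Coefficients are
mapped back to the conventional basis for reporting and prediction, which is
invariant to the rotation.

Initial values: beta from a Poisson GLM, log theta = 0, SDs = 0.1, rho at
the median pairwise station distance.  Bounds keep log-SDs in [-6, 3] and
log-rho within e^±(5-6) of its start; a variance component ending at a bound
triggers up to three random restarts.  Convergence is declared when the
optimizer succeeds and the gradient max-norm is below 1e-3 × max(1, |nll|).
A 1e-8 diagonal jitter is added to every exponential correlation matrix
before factorization.  Exact zero distances (duplicate positions) are
collapsed before sampling, so coincident points receive identical field
values.

Model comparison uses AICc = -2ℓ + 2k + 2k(k+1)/(n-k-1) with k counting
fixed effects, the dispersion, and all variance/range parameters.
Goodness of fit uses randomized quantile residuals: the observed count's
rank among simulated responses (conditional on the estimated random
effects), uniformized with the standard tie-randomization; a KS uniformity
test and a simulation-based Pearson dispersion test are reported.

## Prediction and bias correction

Fleet-level totals are sums of exp(·) of jointly Gaussian quantities, so the
plug-in sum at the posterior mode underestimates the expectation.  Each row
is corrected with half its Laplace-posterior linear-predictor variance:

    T = Σ_i exp(x_i'beta + z_i'u-hat + z_i' Q z_i / 2 + sigma_new^2 / 2),

Q the posterior covariance of the random effects; sigma_new^2 is the prior
variance of random-effect levels absent from the EM data (unmonitored
vessels, years outside the fit, rectangles with no fitted field value — for
those the spatial contribution is sigma_s^2).  Convexity guarantees
T ≥ plug-in, asserted as an invariant and checked against a 10^6-draw
Monte-Carlo oracle on a shared-intercept toy.

Uncertainty: the default standard error is a delta-method computation over
the joint Gaussian approximation of (beta, v) at fixed variance parameters.
The reporting-grade interval is a parametric bootstrap: B draws of the full
parameter vector from the finite-difference-Hessian Gaussian, each combined
with a conditional random-effect draw from the Laplace posterior and fresh
prior draws for unseen levels; percentile intervals of the recomputed
totals.  The resampling scheme for the published intervals is not described
beyond "bootstrapped", so this parametric scheme is the package's documented
choice.  B defaults to 100 000 in production configs and 2000 in tests.

## Standardization

On the link scale the prediction splits into an effort-related part (mesh,
vessel class, net-length, soak-time, mesh × soak, vessel intercept) and a
porpoise-density-related part (population, depth, year intercept, spatial
field).  Freezing the density part at a constant (default: its median over
the prediction rows) and summing predictions gives the standardized effort
index; freezing the effort part gives the standardized BPUE index.  Both are
relative indices — only ratios are meaningful — and their product reproduces
the unstandardized prediction up to one global constant, which is asserted
at machine precision.  Depth's group membership is genuinely debatable
(operational choice vs habitat); it sits in the density group by default and
the grouping is a configuration list.  The intercept sits in the effort part;
its placement cancels in every ratio.

## Pinger scenarios

The acoustic-deterrent regulation is encoded as data (area × vessel-class ×
mesh × quarter scope tuples), not hard-wired law.  Two totals are produced:
all effort (no deterrent effect) and effort with mandatory-deterrent rows
removed (full compliance, 100% effective deterrence — a deliberate lower
bound).  Removal can only shrink group totals, asserted as a property over
random rule sets.

## Removal limits

Abundance for the Western Baltic assessment unit is density × the summed
Kattegat + Sound + Belt Seas surfaces (20 536 + 2 281 + 17 862 km²), the
area over which bycatch is estimated.  N_min = N / exp(0.842·sqrt(ln(1+CV²)))
is the 20th-percentile estimate; limits are N_min × ½R_max × F_r with
R_max = 0.04 and F_r ∈ {0.5, 1.0} (PBR) or the retuned {0.15, 0.35} (mPBR,
taken as given constants from published robustness trials).  z = 0.842 is
not printed alongside the published table; it is exposed as a parameter and
validated by exact reproduction of the published N_min column.  All rounding
is to the nearest integer, half away from zero, applied to N, N_min and each
limit independently — the convention that reproduces every published cell.
The 2012 abundance is carried as printed (32 136) rather than recomputed,
because the printed density is rounded too coarsely to reproduce it; the
2016 and 2020 abundances reproduce exactly.

## Synthetic data: what it does and does not emulate

The generator draws a fleet of vessels with a fixed length class each;
every vessel-year fishes a set number of distinct calendar days, each day in
one rectangle of a default 17-rectangle region spanning the eastern North
Sea, Skagerrak, Kattegat, Belt Seas and Sound, with region-shaped mean
depths.  Mesh class is drawn per day; soak hours and net metres are
log-normal.  Counts follow exactly the NB2 mixed model above, with fields
drawn per quarter-within-year group at rectangle centroids.  Default true
parameters give an EM bycatch rate of ≈0.05–0.09 porpoises per fishing day,
the order seen in Danish EM monitoring, with effect directions chosen
plausibly (higher risk in 120–200 mm cod-type nets, longer nets and soaks;
lower at depth).

Because counts are generated from the model's own assumptions, passing
tests demonstrate internal correctness and calibration — parameter recovery,
interval coverage, residual uniformity — not robustness to the
misspecifications real logbook data carry (reporting error, preferential
monitoring, trip-level correlation, non-exponential spatial structure).
Positions live on rectangle centroids because that is the resolution of
fleet effort data; within-rectangle variation is not represented.

## Study sizes used by the validation suite

Chosen so each check measures what it claims while the whole suite stays
desk-scale:

- Parameter recovery: 50 datasets, each 25 vessels × 8 years × 10 days
  (n = 2000), full EM coverage; true values theta 1.0, sigma_vessel 0.5,
  sigma_year 0.3, sigma_s 0.6, rho 50 km, intercept −3.9 (≈0.7 bycatch/day,
  so the dispersion and variance components are identifiable at this n).
  Mean fixed effects land within 2 Monte-Carlo SE; theta and the three
  variance components within 15% relative bias.  The spatial range rho is
  right-skewed upward (mean ≈ +19% here) — with 17 stations only
  sigma_s²/rho is well identified, a known property of exponential-range
  ML — so the suite holds it to a 0.5×–2× band rather than the 15% one.
- Stratified bootstrap coverage: 500 replicate fleets, 4 strata with
  Poisson rates 0.08–0.3 and 50 EM days each, B = 5000; coverage must land
  in 92–98%.
- Residual calibration: 20 datasets simulated from one fitted model; KS
  rejections at alpha = 0.05 must not exceed 3 of 20.
- The glmmTMB cross-check fits the identical NB2 vessel+year model in R on
  a 1200-row dataset and must agree in log-likelihood (±0.5), dispersion
  (±5%) and coefficients (±0.05–0.2).

## Known limitations

- The Laplace approximation is first-order; with very low counts per
  latent level the variance components carry a downward bias of a few
  percent to ~13% (measured for sigma_vessel at 25 vessels), as for any
  Laplace-based NB GLMM fit.  No REML-like correction is applied.
- Finite-difference gradients make fitting O(#params) more expensive per
  iteration than an adjoint-based engine; fits of the full model at
  n = 2000 take ~10 s.
- Prediction-interval coverage inherits the Gaussian approximation of the
  parameter sampling distribution; variance-parameter uncertainty enters the
  bootstrap but not the delta-method SE.
- Trip structure is not modelled: the deterrent filter removes fishing-day
  rows, the closest observable unit to the regulation's trip scope in the
  harmonized schema.
- Mesh-class endpoint membership ("120–200" closed on both ends) and
  vessel-class half-open bins are conventions; the class labels alone do not
  pin them down.
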