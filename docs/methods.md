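# Methods

This note documents the models, the estimation machinery, the synthetic
cohort generator, and the numerical and design choices behind
`dietsurv`.

## Models

### Trajectory submodel

A child's daily food consumption y_i(t) (g/day, or g/MJ after energy
adjustment) is modelled as a cubic B-spline mixed model on ages
0.25–6 years: an intercept plus five basis functions (two interior
knots, clamped boundary knots repeated four times), each with a fixed
effect and a subject-level random effect. The random-effects covariance
is diagonal; residuals are independent N(0, sigma^2). The full 6-function
clamped basis is reparameterized to intercept + 5 columns by absorbing
the first basis function into the intercept; the fitted curve is
invariant to this choice (tested under basis-column rescaling, which is
the subclass of reparameterizations that preserves a diagonal
random-effects covariance).

Estimation is maximum likelihood, not REML: the joint models require an
ML likelihood and BIC comparisons across fixed-effect structures are
only valid under ML. Fixed effects are profiled out (GLS at each
variance-parameter value); the 7 log-variances are optimized by
L-BFGS-B with a floor of −12 on each log variance. A floor hit is
reported as a variance estimated at zero (boundary flag). Convergence:
relative log-likelihood change below 1e-12 in the optimizer's scaled
units; observed-information SEs by central finite differences.

BIC uses the number of *subjects* as the sample size, the convention of
the latent-class literature this package interoperates with.

### Interior-knot search

Candidates are the four equispaced points inside each gap of the nominal
measurement schedule; a pair (k1, k2) is admissible when at least two
measurement ages lie before k1, strictly between k1 and k2, and after
k2. Every admissible pair is fitted and the minimum-BIC pair returned,
with ties (within 1e-9) broken toward the smaller first knot then the
smaller second knot, so reporting is deterministic. Boundary knots sit
at the first and last scheduled record ages (0.25, 6.0) — the data exist
only there. The search uses the nominal schedule rather than per-child
ages; the optional 5-year record only densifies the candidate grid.

### Basic joint model

The hazard is h_i(t) = h0(t) exp(gamma' w_i + alpha m_i(t)) with
piecewise-constant h0 (default knots 1.99, 3.99; follow-up 6 years) and
a current-value association. The joint likelihood integrates, per
subject, the product of the longitudinal Gaussian density, the survival
density and the random-effects prior over the 6-dimensional random
effect.

*Quadrature.* Pseudo-adaptive Gauss–Hermite: nodes are centred and
scaled at each subject's empirical-Bayes posterior mode and curvature
from the standalone mixed-model fit and kept fixed across optimizer
iterations (re-centring each iteration in 6 dimensions is prohibitively
slow on one CPU; the fixed centring is the accuracy/speed trade-off and
the node count is configurable, default 3 per dimension = 729 nodes).
An exact low-dimensional path (random intercept only) exists for oracle
testing and agrees with brute-force 1-D integration to 1e-6.

*Hazard integral.* Within each baseline-hazard segment the integrand
exp(alpha m(s)) is smooth, so fixed-order Gauss–Legendre quadrature is
used (default 7 points per segment; 3 points change the log-likelihood
by ~3e-7 relative and are used in the heavy simulation tests).
Integration pieces are split at the spline boundaries: m(s) is extended
*constantly* to the left of the first record age (consumption before
3 months is essentially zero, and m(0.25) estimates it), which puts a
kink in the integrand that would otherwise defeat Gauss–Legendre
accuracy.

*Optimization.* The score has a closed form (posterior-weighted
class-conditional scores over quadrature nodes); the analytic gradient
is validated against finite differences in the tests. Parameters are
optimized by L-BFGS-B after diagonal preconditioning (fixed effects in
g/day units and the association parameter differ by orders of magnitude
in curvature), warm-started by a survival-block-only stage with the
longitudinal block pinned at the mixed-model estimates, with fresh
restarts if a line-search stall leaves a large projected gradient.
Baseline heights initialize at occurrence/exposure rates; alpha and
gamma at zero. The hazard exponent alpha*m is capped at ±50 to keep
absurd line-search iterates finite; no realistic iterate approaches the
cap. SEs come from the observed information computed by central
differences of the analytic gradient.

### Joint latent class mixed model

G classes with class-specific fixed effects and class-specific
piecewise hazards (knots 1.99, 3.99, 5.99; follow-up 15 years), linked
only via class membership; random-effect variances, residual variance
and covariate effects gamma are shared across classes. Sharing the
random-effects covariance across classes is a deliberate choice (it
keeps 6 fewer parameters per extra class and matches common practice);
it is the one place the class-conditional model is restricted. The
multinomial membership model is intercept-only by construction so that
class membership reflects the consumption profiles alone. Because the
hazard does not involve m(t), the random effects integrate analytically
and the class-conditional longitudinal likelihood is a marginal
Gaussian — no quadrature anywhere.

*Estimation.* EM with posterior class probabilities in the E-step; the
M-step uses exact weighted GLS for class fixed effects, a closed-form
EM update for the shared variances (treating random effects as missing
data as well — one linear-algebra pass, monotone), and
occurrence/exposure-profiled hazard heights with a small quasi-Newton
step for gamma. A safeguard stops EM if numerical noise would decrease
the likelihood. Starts: k-means on per-subject trajectory features plus
random hard assignments (default 10 starts); the best likelihood is
polished by L-BFGS-B with an analytic mixture gradient. Classes are
relabelled in descending size order; a class below 1% of subjects is
flagged as spurious.

*Hazard ratios.* Piecewise HRs between the two classes are
exp(xi_2j − xi_1j) with delta-method variances from the full mixture
covariance (not a modal-assignment refit — the full covariance
propagates classification uncertainty). Intervals must align with
hazard segments (1.99≈2 etc.). In segments where the smaller class has
almost no events the log-HR is unidentified and its SE explodes; this
mirrors the behaviour of sparse real cohorts and is left visible rather
than masked. The overall HR refits the model with h02 = theta*h01 and
reports exp(log theta) with a Wald CI; the constrained likelihood can
never exceed the unconstrained one (nesting, tested).

*Class number.* Minimum BIC plus a diagnostics table (mean modal
posterior per class, smallest class share, relative entropy); exact BIC
ties go to the smaller G. The final call stays overridable — class
enumeration is a judgment-supported decision, not an automatic one.

### Step-function Cox comparator

The counting-process table carries the last recorded (multiply imputed
3-day mean) intake forward to the next record; events sit at interval
midpoints; administrative censoring at 6 years matches the joint model's
window. The partial likelihood (Breslow ties by default, Efron by flag)
is implemented directly so both tie conventions share one code path; it
is cross-checked against an exhaustive risk-set product and against
lifelines. Children whose endpoint precedes their first food record are
excluded and logged, mirroring the cohort's inclusion criterion.
`impute_3day_mean` is a simplified, clearly labelled stand-in for the
registry imputation procedure: missing days draw from a normal centred
on the occasion's observed-day mean with an age-pooled day-to-day SD.

### Sensitivity machinery

Interval-censoring MI draws event times from a marginal
piecewise-exponential model conditioned to each (L, R] interval,
refined once, refits, and pools by Rubin's rules. The one-refinement
scheme is this package's documented choice. Baseline-hazard knot
perturbation refits with one knot removed/added, new knots at
event-time quantiles so intervals hold equal event counts. The delete-5
jackknife uses random 5-subject deletions (enumeration of all C(n,5)
subsets is infeasible) with the (n−d)/d variance scaling.

## Synthetic cohort generator

The generator *is* the study design: defaults are the cohort conditions,
not test conveniences.

- Baseline covariates: 53.2% boys, 19.6% high genetic risk, 5.9%
  familial diabetes (3.9% missing), n = 5545 by default.
- Food records at 0.25, 0.5, 1, 2, 3, 4, 6 years, plus an optional
  5-year record per child (probability 0.25 — the source protocol says
  only that "some" children had one).
- Antibody visits every 0.25 y to age 2, every 0.5 y to 6, yearly to 15
  (the protocol states 3-to-12-month intervals without the full grid).
- Dropout: independent exponential with rate 0.0739/y, truncated to the
  visit grid; this reproduces the marginal retention pattern
  (~93%/86%/64%/33% at 1/2/6/15 y) with a single parameter, since only
  marginal retention fractions are known. The first visit is always
  attended (children without any autoantibody measurement would fail
  the cohort's inclusion criterion).
- Meat-like trajectory truth: 0 g/day at 3 months rising to a mean of
  88 g/day at 6 years, between-subject SD ~50 and day-to-day SD 35 at
  age 6 (total ~61); association alpha = log(1.06)/10; baseline hazard
  calibrated to ~4.4% detected incidence by 6 years.
- Fish-like two-class truth: 83.3%/16.7% mixture; low consumers flat
  near 5 g/day from age 1, high consumers climbing to 25 g/day at 6
  years; class-2 hazard 0.68 × class-1 in every interval. Class hazard
  heights are calibrated so the *detected* 15-year incidence is ~6.3%:
  interval censoring plus dropout detects only ~2/3 of true events, so
  true cumulative incidence is correspondingly higher.
- Event times: inverse-sampling of the subject-specific cumulative
  hazard, integrated by trapezoid on a 2001-point grid (configurable)
  and matched to a standard-exponential draw by monotone interpolation.
  A Kolmogorov–Smirnov test against an independently computed CDF
  guards the sampler.
- Energy intake: lognormal around an age-increasing mean (2 MJ/day at
  3 months to 6.5 MJ/day at 6 years, CV ~18%) — simulated directly; no
  breastfeeding or growth chain.
- Negative intakes from Gaussian noise are kept by default (the fitted
  model assumes them; flooring at zero breaks exact parameter
  recovery); an optional floor-at-zero switch records a `floored` flag.

What the generator does **not** emulate: reporting error correlated
with diet, visit-schedule dependence on symptoms, seasonal intake
patterns, within-occasion (3-day) structure except through
`impute_3day_mean` inputs, and covariate-dependent class membership.
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that the model is right for any real cohort.

## Problem sizes in the test suite

The acceptance-style experiments run at sizes chosen for a single CPU:
hazard-ratio recovery at truth 1.06 uses 10 replicate cohorts of
n = 2000 (3-node quadrature, 3-point Gauss–Legendre); the attenuation
contrast 10 replicates of n = 500 with day-to-day SD 55 and truth HR
1.20 per 10 g; two-class modal accuracy one cohort of n = 2000;
proportional-HR coverage 20 replicates of n = 500 and null calibration
200 replicates of n = 300 with event rates boosted (×3 baseline) so
each replicate carries a usable event count; the step-function Cox
calibration 400 null replicates of n = 300. The knot-search recovery
experiment uses the 7-point schedule without the 5-year record and
n = 250 per replicate.

## Known limitations

- Pseudo-adaptive quadrature with 3 nodes/dimension is accurate for
  these noise levels but has no interior error estimate; the node count
  is configurable and a 3-vs-5-node stability check is part of the
  tests.
- The JLCMM does not support class-specific random-effect covariances
  or covariate-dependent membership (deliberate scope).
- Only a current-value association is implemented for the joint model
  (no slope/cumulative/lagged structures).
- Wald inference for the proportional-baseline theta is anticonservative
  when the smaller class carries very few events; the calibration test
  documents the regime (tens of events) where it is nominal.
- The interval-censoring MI uses a marginal piecewise-exponential
  imputation model; with strongly covariate-dependent hazards a
  conditional model would be preferable.
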