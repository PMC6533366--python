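# dietsurv

Joint models for longitudinal dietary exposure and interval-censored
disease onset.

## The problem

Nutritional cohort studies measure a child's food consumption a handful
of times (3-day food records at 3 and 6 months and at 1, 2, 3, 4 and 6
years) while following the child for a disease endpoint — here, advanced
islet autoimmunity or type 1 diabetes, detected only between autoantibody
visits (interval censoring). The conventional analysis is a Cox
regression with the last recorded intake carried forward as a step
function (CRM). Day-to-day intake variation and the crude step
approximation attenuate that estimate toward the null. This package
implements the two joint-modelling alternatives, the naive comparator,
and a synthetic cohort generator with known ground truth, so each
estimator can be validated by parameter recovery.

**Basic joint model (JM).** A cubic B-spline mixed model for the true
trajectory m_i(t), linked to a relative-risk model through its current
value:

    y_i(t) = m_i(t) + e_i(t),   m_i(t) = b0 + b0i + sum_k (bk + bki) Bk(t)
    h_i(t) = h0(t) exp{gamma' w_i + alpha m_i(t)}

with diagonal random-effects covariance, N(0, sigma^2) errors, and a
piecewise-constant baseline hazard h0 (knots 1.99 and 3.99 years,
administrative censoring at 6 years). Both submodels are estimated
simultaneously by maximizing the joint likelihood, integrating the
6-dimensional random effects by pseudo-adaptive Gauss–Hermite
quadrature. The food effect is reported as exp(10 alpha) per 10 g/day
(per 1 g/MJ when energy-adjusted).

**Joint latent class mixed model (JLCMM).** A G-class mixture: each class
has its own spline trajectory and its own piecewise baseline hazard
(extra knot at 5.99 years, follow-up to 15 years); the submodels are
linked only through class membership, whose probabilities come from an
intercept-only multinomial model:

    y_i(t) | c_i=g = b0g + b0ig + sum_k (bkg + bkig) Bk(t) + e_i(t)
    h_i(t) | c_i=g = exp{gamma' w_i} h0g(t)
    Pr(c_i = g)    = exp(lambda_g) / sum_l exp(lambda_l)

Class-number choice uses BIC plus discrimination diagnostics; per-interval
hazard ratios between classes get delta-method CIs, and an overall ratio
comes from a proportional-baseline refit (h02 = theta * h01).

The spline's two interior knots are selected by fitting the mixed model
at every admissible candidate pair (four equispaced candidates per gap of
the measurement schedule, at least two measurements before, between and
after the knots) and minimizing BIC.

## Worked example

```bash
python examples/fit_joint_model.py
```

prints (seeded, so exactly reproducible):

```
converged: True   events: 62
term    hr    lo    hi     p
food 0.988 0.827 1.179 0.891

true food HR per 10 g/day: 1.060
```

A cohort of 1500 children is generated under the joint model with a true
hazard ratio of 1.06 per 10 g/day, then refitted from scratch. The
`food` row is the estimated hazard ratio for the current true intake
with its 95% Wald CI; with only 62 events one replicate is noisy (here
0.99, CI 0.83–1.18, covering the truth), and across replicates the mean
estimate centres on 1.06 — the recovery experiment in
`tests/test_acceptance.py` checks exactly that. The other examples cover
the simulator, the latent-class analysis, the step-function Cox
comparator with energy adjustment and interval-censoring sensitivity,
and the spline knot search:

```bash
python examples/simulate_cohort.py
python examples/latent_classes.py
python examples/step_function_cox.py
python examples/knot_search.py
```

A thin CLI wraps the same functions (`dietsurv simulate`,
`dietsurv fit-jm`, `dietsurv fit-jlcmm`, `dietsurv pipeline`).

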