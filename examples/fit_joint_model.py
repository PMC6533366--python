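"""Fit the shared-random-effects joint model on a simulated cohort.

The longitudinal submodel is a cubic B-spline mixed model; the hazard at
age t is h0(t) * exp(gamma'w + alpha * m(t)) with the *current true*
consumption m(t) as the time-dependent exposure.  The printed table shows
the hazard ratio per 10 g/day of consumption and per baseline contrast."""

import numpy as np

from dietsurv import CohortConfig, QuadConfig, default_jm_truth, fit_jm, \
    simulate_cohort

truth = default_jm_truth(hr_per_10g=1.06, adjusted=False)
coh = simulate_cohort(CohortConfig(n_subjects=1500, followup_max=6.0,
                                   seed=3), truth)
fit = fit_jm(coh.long, coh.endpoints, None, truth.spec,
             hazard=truth.hazard, config=QuadConfig(nodes=3, gl_points=3))

print(f"converged: {fit.converged}   events: {fit.n_events}")
print(fit.hr_table(food_increment=10.0).round(3).to_string(index=False))
print(f"\ntrue food HR per 10 g/day: "
      f"{np.exp(10 * truth.params.alpha):.3f}")
# The 'food' row estimates the association between the current true
# intake and the hazard; with 1500 children and ~60 events its CI is
# wide, but the point estimate centres on the generating value across
# replicates.
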