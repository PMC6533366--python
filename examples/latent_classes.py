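"""Two-class joint latent class mixed model on fish-like trajectories.

A small class of high consumers (climbing to ~25 g/day by age 6) is mixed
with a large low-consumer class (~5 g/day); each class carries its own
piecewise-constant baseline hazard.  The example prints the class sizes,
the per-interval hazard ratios (high vs low consumers) with delta-method
CIs, and the overall proportional-hazards ratio."""

import dataclasses

import numpy as np

from dietsurv import (CohortConfig, JlcmmConfig, fit_jlcmm,
                      overall_hr_proportional, piecewise_hr,
                      separated_jlcmm_truth, simulate_latent_class_cohort)

truth = separated_jlcmm_truth(overall_hr=0.68)
# triple the baseline hazards so the smaller class carries enough events
# for its per-interval ratios to be estimable at this cohort size
truth = dataclasses.replace(
    truth,
    params=dataclasses.replace(
        truth.params, log_heights=truth.params.log_heights + np.log(3.0)
    ),
)
coh = simulate_latent_class_cohort(CohortConfig(n_subjects=1500, seed=99),
                                   truth)
cfg = JlcmmConfig(starts=2, seed=5)
fit = fit_jlcmm(coh.long, coh.endpoints, coh.baseline, truth.spec, G=2,
                config=cfg)

acc = (fit.modal == coh.labels).mean()
print(f"class sizes (modal): {fit.class_sizes.tolist()}  "
      f"label accuracy: {max(acc, 1 - acc):.1%}")
print("\npiecewise hazard ratios, high vs low consumers:")
print(piecewise_hr(fit).round(3).to_string(index=False))

prop = overall_hr_proportional(coh.long, coh.endpoints, coh.baseline,
                               truth.spec, config=cfg, init_fit=fit)
print(f"\noverall HR (proportional hazards): {prop.hr:.2f} "
      f"({prop.lo:.2f}, {prop.hi:.2f})  P = {prop.p:.3f}   "
      f"[truth 0.68]")
# Intervals with few events in the small class have very wide CIs - the
# same behaviour the delta-method SEs show on sparse real cohorts.
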