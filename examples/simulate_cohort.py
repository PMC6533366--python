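"""Generate a synthetic birth cohort and summarize it.

The generator emulates a prospective infant-feeding cohort: food records
on the nominal schedule (3 and 6 months; 1, 2, 3, 4, optionally 5, and 6
years), autoantibody visits every 3-12 months, staggered dropout, and an
interval-censored disease endpoint."""

import numpy as np

from dietsurv import CohortConfig, simulate_latent_class_cohort, write_cohort

cfg = CohortConfig(n_subjects=2000, seed=20190523)
coh = simulate_latent_class_cohort(cfg)

print(f"subjects            : {len(coh.baseline)}")
print(f"food records        : {len(coh.long)}")
print(f"boys                : {(coh.baseline.sex == 'boy').mean():.1%}")
print(f"high-consumer class : {(coh.labels == 1).mean():.1%}")
print(f"detected events     : {coh.endpoints.event.sum()} "
      f"({coh.endpoints.event.mean():.1%} by 15 y)")
by_age = coh.long.groupby("age_years")["food_g_day"].mean()
print("mean intake (g/day) by age:")
print(by_age.round(1).to_string())

write_cohort(coh, "scratch/example_cohort")
print("cohort written to scratch/example_cohort/")
# The detected-event fraction sits near the 6.3% cumulative incidence the
# cohort design targets; the two trajectory classes mix 83%/17%.
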