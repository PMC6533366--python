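"""The naive comparator: Cox regression with the exposure carried forward
as a step function, with energy adjustment and an interval-censoring
sensitivity analysis.

Under day-to-day intake noise the step-function estimate attenuates
toward HR = 1 relative to the joint model - the motivating methodological
contrast of this package."""

import numpy as np

from dietsurv import (CohortConfig, build_counting_process, default_jm_truth,
                      energy_adjust, fit_cox_td, mi_interval_censored,
                      simulate_cohort)

truth = default_jm_truth(hr_per_10g=1.20, adjusted=False)
truth.params.log_sigma2 = float(np.log(55.0 ** 2))  # heavy day-to-day noise
coh = simulate_cohort(CohortConfig(n_subjects=1500, followup_max=6.0,
                                   seed=17), truth)

cp = build_counting_process(coh.long, coh.endpoints, followup_max=6.0)
crm = fit_cox_td(cp, ["exposure"])
print("step-function Cox, per 10 g/day:")
print(crm.hr_table().round(3).to_string(index=False))
print(f"(generating truth: HR {np.exp(10 * truth.params.alpha):.2f} "
      "- the step-function estimate is attenuated toward 1)")

adj = energy_adjust(coh.long)
cp_e = build_counting_process(adj, coh.endpoints, followup_max=6.0,
                              exposure_col="food_g_mj")
crm_e = fit_cox_td(cp_e, ["exposure"], exposure_increment=1.0)
print("\nenergy-adjusted, per 1 g/MJ:")
print(crm_e.hr_table().round(3).to_string(index=False))


def crm_fitter(endpoints):
    cpt = build_counting_process(coh.long, endpoints, followup_max=6.0)
    f = fit_cox_td(cpt, ["exposure"])
    return float(f.coef[0]), float(f.cov[0, 0])


mi = mi_interval_censored(coh.endpoints, crm_fitter, m=5, seed=1)
print("\ninterval-censoring sensitivity (log-HR per g/day):")
print(f"  midpoint fit : {mi['midpoint']['estimate']:+.5f} "
      f"(SE {mi['midpoint']['se']:.5f})")
print(f"  MI pooled    : {mi['pooled']['estimate']:+.5f} "
      f"(SE {mi['pooled']['se']:.5f})")
# The pooled estimate stays close to the midpoint analysis while its SE
# grows slightly - interval censoring adds uncertainty, not bias, here.
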