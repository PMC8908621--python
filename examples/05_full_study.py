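"""The whole study in one call: naive and instrumental-variable analyses
per sidedness subgroup, endogeneity tests, interaction tests, and the
cross-side correlation of regional treatment rates.

The scenario generates a left-sided survival benefit of PMTR (true HR
0.37) and none on the right, under unmeasured confounding that biases the
naive model toward the null.
"""

import warnings

from ivsurv import generate_cohort, run_full_study, scenario_library

cfg = scenario_library("sided_benefit", seed=9)
cohort, truth = generate_cohort(cfg)
coords = {h: (r["x"], r["y"]) for h, r in truth.regions.items()}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = run_full_study(cohort, coords, seed=9)

print(f"eligible patients: {res['n_eligible']}")
for key, a in res["analyses"].items():
    med = a["median_os"]
    print(f"\n{key}")
    print(f"  IV    HR {a['hr']:.2f} [{a['ci_low']:.2f}, {a['ci_high']:.2f}]"
          f"  p={a['p']:.3f}   (F={a['f_statistic']:.0f}, "
          f"DWH p={a['dwh_p']:.3f})")
    print(f"  naive HR {a['naive_hr']:.2f} "
          f"[{a['naive_ci'][0]:.2f}, {a['naive_ci'][1]:.2f}]")
    print(f"  median OS {med['treated']['median']:.0f} vs "
          f"{med['control']['median']:.0f} months "
          f"(n = {a['n_per_arm']['treated']} vs {a['n_per_arm']['control']})")
print(f"\ninteraction p (PMTR effect, left vs right): "
      f"{res['interaction_p']['pmtr_vs_other']:.4f}")
print(f"cross-side PMTR-rate correlation r = "
      f"{res['pmtr_rate_correlation']['r']:.2f} "
      f"over {res['pmtr_rate_correlation']['n_regions']} regions")
print("\nReading: the IV hazard ratio for left-sided disease should sit "
      "near the simulated truth 0.37 while the naive estimate is biased "
      "toward 1 by the unmeasured confounder.")
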