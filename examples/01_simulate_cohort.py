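"""Generate a synthetic registry cohort and inspect its structure.

The generator emulates a stage-IV colorectal registry: regions (health
service areas) with different surgical practice styles, an unmeasured
confounder that drives both treatment choice and mortality, and
exponential survival with administrative censoring.
"""

from ivsurv import generate_cohort, scenario_library

cfg = scenario_library("sided_benefit", seed=1)
cohort, truth = generate_cohort(cfg)

print(f"patients: {len(cohort)}, regions: {len(truth.regions)}")
print(f"event fraction: {truth.event_fraction:.3f}")
print(cohort[["patient_id", "hsa_id", "site_code", "surgery_primary",
              "surgery_mets", "followup_months", "event"]].head())

rates = cohort.groupby("hsa_id").apply(
    lambda g: ((g.surgery_primary == "yes") & (g.surgery_mets == "yes")).mean(),
    include_groups=False)
print(f"\nregional PMTR rates: min {rates.min():.3f}, median "
      f"{rates.median():.3f}, max {rates.max():.3f}")
print("The spread of regional rates is the raw material of the instrument:")
print("it reflects practice style, not patient severity.")
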