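"""Generate a small virtual-patient cohort and summarize its records.

Each patient is a 14-day closed-behavioral-loop simulation: Gaussian meals
(means 50/60/63.5 g, 20% CV), carb-counting error, therapy boluses against
preprandial SMBG, circadian-following basal, 20-g rescues below 60 mg/dl,
and a lagged noisy CGM sensor sampled every 5 min.
"""

import numpy as np

from glucoge import ScenarioConfig, simulate_cohort

datasets, manifest = simulate_cohort(5, ScenarioConfig(), master_seed=1)

print(f"{len(datasets)} patients x {datasets[0].n_days} days, "
      f"{len(datasets[0].cgm)} CGM samples each")
print(manifest[["patient_id", "seed", "body_scale", "insulin_sens", "cr", "cf"]]
      .round(3).to_string(index=False))

for pid, ds in enumerate(datasets):
    cgm = ds.cgm.values
    meals = [e for e in ds.cho_events if e not in ds.hypotreatments]
    print(f"patient {pid}: CGM mean {cgm.mean():6.1f} mg/dl "
          f"[{cgm.min():.0f}-{cgm.max():.0f}], "
          f"{len(meals)} meals, {len(ds.hypotreatments)} rescues, "
          f"{len(ds.insulin.boluses)} boluses")
print("(rescues are always 20 g and >= 20 min apart; boluses occur only at"
      " meal times)")
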