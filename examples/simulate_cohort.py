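"""Generate a synthetic labeled ICU cohort and inspect its structure.

Builds 100 admissions at the default study conditions, prints the stratum
breakdown, label balance and reward statistics, and writes the trajectory
CSV plus the strata sidecar. Strata counts show how common failed weans
(multiple intubation) are; the reward mean reflects the per-step vitals
score minus the ventilator cost plus occasional wean bonuses.
"""

from collections import Counter
from pathlib import Path

import numpy as np

from icusac import SimulatorConfig, build_stage_arrays, simulate_cohort
from icusac.io import write_strata_csv, write_trajectories_csv

cohort = simulate_cohort(SimulatorConfig(n_admissions=100, seed=11))
arrays = build_stage_arrays(cohort, "vent")

print(f"admissions: {len(cohort)},  transitions: {len(arrays)}")
print("strata:", dict(Counter(t.stratum.value for t in cohort)))
print(f"wean-action fraction: {np.mean(arrays.actions):.3f}")
print(f"reward per step: mean {arrays.rewards.mean():.3f}, "
      f"min {arrays.rewards.min():.1f}, max {arrays.rewards.max():.1f}")

out = Path("scratch/example_cohort")
out.mkdir(parents=True, exist_ok=True)
write_trajectories_csv(cohort, out / "trajectories.csv")
write_strata_csv(cohort, out / "strata.csv")
print(f"wrote {out / 'trajectories.csv'}")
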