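"""Generate a small two-group synthetic cohort and inspect its ground truth.

The generator plants five microstate classes with group-specific dwell
times (patients: shorter class C, more frequent class D) and records, for
every subject, the exact state sequence and the dynamic features counted
from it.
"""

import pandas as pd

import microdyn as md

config = md.SimulationConfig(n_per_group=4, duration=60.0, seed=7)
recordings, truths, sheet = md.simulate_cohort(config)

print(f"cohort: {len(recordings)} subjects, "
      f"{recordings[0].n_channels} channels, "
      f"{recordings[0].duration:.0f} s at {config.sampling_rate:.0f} Hz\n")
print(sheet.to_string(index=False))

truth_table = pd.concat(
    t.features.assign(subject=t.subject, group=t.group) for t in truths)
summary = truth_table.groupby(["group", "class_index"])[
    "mean_duration_ms"].mean().unstack()
print("\nplanted mean dwell time (ms) per class, averaged over subjects:")
print(summary.round(1).to_string())
print("\nClass C (index 2) dwells shorter in patients than controls, and"
      "\nclass D (index 3) longer -- the planted group contrast that the"
      "\nanalysis pipeline is supposed to recover from the raw signals.")
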