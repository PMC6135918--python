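"""Run the complete two-group microstate analysis on a synthetic cohort.

Simulates a small insomnia-vs-control style cohort, runs two-level
clustering with class-count selection, canonical A-E labeling,
back-fitting, feature extraction, and the group statistics: mixed-model
contrasts for duration/occurrence, Dirichlet regression for coverage,
per-class TANOVA, and the family-wise error threshold.
"""

import numpy as np

import microdyn as md
from microdyn.pipeline import summarize_features

config = md.SimulationConfig(n_per_group=8, duration=60.0, seed=42)
recordings, truths, sheet = md.simulate_cohort(config)
result = md.run_pipeline(recordings, sheet, seed=1, n_restarts=10,
                         n_perm=999)

gm = result.group_model
print(f"group-level classes: k* = {gm.k_star}, labeled "
      f"{', '.join(gm.canonical_labels)}")
print(f"class-count agreement (pooled / per group): {result.kl_agreement}")
gev = np.mean(list(gm.gev_per_subject.values()))
print(f"mean global explained variance at GFP peaks: {gev:.1f} %\n")

summary = summarize_features(result.features)
print("group summaries and effect sizes (patient minus control):")
print(summary.round(2).to_string(index=False))

print("\nmodel-based group contrasts per class "
      f"(FWER threshold {result.fwer_threshold:.4g}):")
print(result.effects.round(4).to_string(index=False))

print("\nTANOVA p per class (topographic group difference):")
print(result.tanova.round(3).to_string(index=False))
print("\nWith only 8 subjects per group the planted dwell-time contrasts "
      "(shorter C, busier D in patients)\nshow up as medium effect sizes; "
      "topographies do not differ, so TANOVA p-values are large.")
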