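"""Compare back-fitting at GFP peaks only versus at every timeframe.

The dynamic features can be extracted from labels assigned only at the
GFP local maxima (the default) or at every sample.  On sufficiently long
recordings the two variants rank subjects almost identically, so either
timescale carries the same between-subject information.
"""

import microdyn as md

config = md.SimulationConfig(n_per_group=4, duration=120.0, seed=5)
recordings, _, sheet = md.simulate_cohort(config)
result = md.run_pipeline(recordings, sheet, seed=1, n_restarts=6,
                         run_stats=False)

conditioned = [md.bandpass_and_reref(r) for r in recordings]
peaks_table = md.feature_table(conditioned, result.group_model, sheet,
                               at_peaks_only=True)
frames_table = md.feature_table(conditioned, result.group_model, sheet,
                                at_peaks_only=False)
equivalence = md.peak_vs_frame_equivalence(peaks_table, frames_table)

print("across-subject Pearson r between the two fitting variants,")
print("per class x feature:\n")
print(equivalence.round(3).to_string(index=False))
print(f"\nmedian r = {equivalence['r'].median():.3f} over "
      f"{len(sheet)} subjects at {config.duration:.0f} s each.")
print("High correlations mean the choice of fitting timescale barely "
      "matters for\ngroup comparisons; correlations tighten further as "
      "recordings get longer.")
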