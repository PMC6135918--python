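"""Pooled-SD effect sizes from published group summary statistics.

Given only group means and standard deviations of a dynamic feature (as
printed in a paper's table), Cohen's d is recomputable exactly.  The
convention is patients minus controls: positive d means the feature is
larger in the patient group.
"""

import microdyn as md

n = 32  # subjects per group

examples = [
    # feature, class, control mean/sd, patient mean/sd
    ("occurrence (1/s)", "D", 3.80, 1.61, 4.45, 1.09),
    ("mean duration (ms)", "B", 57.55, 11.02, 53.54, 7.89),
    ("mean duration (ms)", "C", 60.71, 16.74, 52.69, 11.09),
    ("coverage (%)", "D", 22.93, 9.92, 28.02, 9.88),
]

print(f"{'feature':20s} {'class':5s} {'control':>14s} {'patient':>14s} "
      f"{'d':>6s}")
for feat, cls, m1, s1, m2, s2 in examples:
    d = md.cohens_d(m1, s1, n, m2, s2, n)
    print(f"{feat:20s} {cls:5s} {m1:7.2f}±{s1:5.2f} {m2:7.2f}±{s2:5.2f} "
          f"{d:6.2f}")

print("\nClass D occurs more often (d ≈ 0.47) and class C dwells shorter "
      "(d ≈ -0.57)\nin patients: medium effects of the kind reported for "
      "insomnia cohorts.")
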