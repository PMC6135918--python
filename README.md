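# microdyn

Resting-state EEG **microstate** analysis for two-group (case–control)
designs, built as an importable Python library with a thin command-line
wrapper, plus a synthetic cohort generator with planted ground truth.

Resting EEG can be partitioned into brief (~50–100 ms) periods during
which the scalp voltage topography stays quasi-stable — microstates —
that fall into a handful of recurring classes (canonically labeled
A, B, C, D, E).  How long each class dwells, how often it occurs, and
what fraction of time it covers are compact descriptors of large-scale
brain network dynamics, and they differ between clinical groups (for
example, shorter class-C durations and more frequent class-D microstates
have been reported in insomnia disorder).  `microdyn` implements the full
chain from cleaned multichannel EEG to those group comparisons, for
researchers who want a transparent, fully tested, scriptable version of
the procedure — and a generative model to validate it against.

## The method

1. **Conditioning** — 1–40 Hz zero-phase band-pass, common average
   reference over scalp channels.
2. **GFP peaks** — the global field power
   `GFP(t) = sqrt(mean_i v_i(t)^2)` is the spatial SD of each map; its
   strict local maxima are the clustering atoms.
3. **Polarity-invariant k-means** — maps are compared by absolute spatial
   correlation (a map and its sign-flip are the same state); templates
   are dominant eigenvectors of their assigned maps; dispersion is
   `W(k) = sum (1 - |corr|)`.
4. **Class-count selection** — the Krzanowski–Lai criterion
   `KL(k) = |DIFF(k)| / |DIFF(k+1)|` with
   `DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k)`, maximised over
   k = 3..11, applied per subject and again at the group level, where
   each subject's templates must map to `min(k*_i, k)` distinct group
   classes.
5. **Back-fitting and features** — group templates are assigned
   competitively at GFP peaks; equal-label runs merge into microstates
   bounded by midpoints to neighbouring peaks; per class this yields
   mean duration (ms), occurrence (1/s) and coverage (%).
6. **Statistics** — pooled-SD Cohen's *d*; TANOVA (permutation test on
   the global dissimilarity of group-mean maps); linear mixed-effects
   contrasts (Wald z) for duration and occurrence; Dirichlet regression
   for coverage (compositional, sums to 100%); familywise threshold
   `0.05 / (2 k*)`.

The synthetic generator plants all of it: a semi-Markov state sequence
(gamma dwell times with group-specific means), canonical-style template
topographies, a rectified 10 Hz carrier, spatially correlated band-
limited noise at a configurable GFP signal-to-noise ratio, and exact
per-subject ground-truth features.  See `docs/methods.md` for details
and design rationale.

## Worked example

`examples/full_pipeline.py` simulates 8 + 8 subjects (60 s each at
250 Hz, snr 4) and runs the whole analysis:

```
group-level classes: k* = 5, labeled E, D, A, C, B
class-count agreement (pooled / per group): {'pooled': 5, 'control': 5, 'patient': 5}
mean global explained variance at GFP peaks: 88.0 %

group summaries and effect sizes (patient minus control):
 class_index class          feature  control_mean  control_sd  patient_mean  patient_sd  cohens_d
           0     E mean_duration_ms         54.99        6.71         51.63        6.44     -0.51
           1     D mean_duration_ms         60.54        6.79         65.43        9.66      0.59
           1     D occurrence_per_s          3.51        0.38          4.04        0.47      1.23
           3     C mean_duration_ms         59.78        6.67         58.20        6.22     -0.24
...

model-based group contrasts per class (FWER threshold 0.005):
 class_index  estimate     se       z      p  converged singular          feature
           1    0.5387 0.2050  2.6272 0.0086       True     True occurrence_per_s
...
```

The data-driven class count is 5 (matching the planted model) and the
selection agrees between groups; back-fitting explains 88% of the
GFP-weighted topographic variance at the peaks; and the planted
"busier class D" contrast reappears (occurrence d = 1.23, mixed-model
z = 2.6).  With only 8 subjects per group the remaining effects are
noisy, as the printed summaries show.  Other examples generate
cohorts (`simulate_cohort.py`), walk through single-subject clustering
and the KL curve (`cluster_single_subject.py`), compare the two
back-fitting timescales (`peak_vs_frame.py`), and recompute published
effect sizes from group summary statistics
(`effect_sizes_from_summaries.py`).

The CLI wraps the same pipeline for shell use:

```sh
microdyn simulate --out data/              # synthetic cohort + ground truth
microdyn run data/sample_sheet.tsv --out results/
microdyn report results/                   # per-class summary table
```

All artifacts are plain text (TSV tables, JSON models and manifests).

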