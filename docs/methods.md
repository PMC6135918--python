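# Methods

`microdyn` implements the resting-state EEG microstate analysis chain for
two-group case-control designs, together with a synthetic cohort
generator that provides planted ground truth for every stage.  This note
describes the models, the numerical choices, what the generator does and
does not emulate, and the problem sizes the test suite runs at.

## Signal conditioning and GFP peaks

Cleaned multichannel EEG (artifact removal is assumed done upstream; the
package only consumes a per-sample usable mask) is band-pass filtered at
1–40 Hz with a 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), so the filter is zero-phase and peak
latencies are preserved, then re-referenced to the common average over
scalp channels.  The global field power is the spatial standard deviation
of each average-referenced frame,

    GFP(t) = sqrt( (1/N) Σ_i v_i(t)² ).

GFP local maxima are strict (`gfp(t−1) < gfp(t) > gfp(t+1)`), require
both neighbours unmasked, and a flat maximum contributes its first sample
(deterministic, order-independent).  Topographies at these peaks — the
moments of highest topographic signal-to-noise — are the clustering
atoms.

## Polarity-invariant clustering

A scalp map and its sign-flip express the same generator configuration,
so all comparisons use the absolute spatial (Pearson) correlation across
channels.  Maps are average-referenced and scaled to unit GFP, after
which the correlation is a plain dot product over the channel count.

The modified k-means assigns each map to the template with maximal
|correlation| and recomputes each template as the dominant eigenvector of
the outer-product sum of its assigned maps — the polarity-invariant
centroid.  The eigenvector is found by power iteration warm-started from
the current template (tolerance 1e-12; verified against a dense
eigensolver in the tests).  Iterations stop when the assignment is
unchanged or after 100 sweeps; the best state seen within a run (by
dispersion) is kept, as is the best of `n_restarts = 20` random
initialisations.  Empty clusters are reseeded from the worst-fitted maps.
Dispersion is

    W(k) = Σ_maps (1 − |corr(map, assigned template)|),

the quantity plotted as "within-cluster global dissimilarity" in
microstate work.  A squared-loss alternative was considered and rejected
to keep the criterion aligned with the assignment rule.

### Class-count selection

The Krzanowski–Lai criterion is evaluated on W(k) with the data
dimensionality p set to the number of scalp channels:

    DIFF(k) = (k−1)^(2/p) · W(k−1) − k^(2/p) · W(k)
    KL(k)   = |DIFF(k)| / |DIFF(k+1)|

and the selected count maximises KL over k = 3..11 (so W is computed for
k = 2..12).  Candidates with a zero denominator are excluded; ties break
toward the smaller k.  The KL tail is fragile when the dispersion curve
is noisy: a restart that underperforms at some k can make DIFF(k+1)
nearly vanish and spuriously inflate KL(k).  To keep W non-increasing in
k by construction, each k additionally receives one *incremental*
initialisation — the selected (k−1)-solution extended by the
worst-fitted map as a new template — whose starting dispersion is at
most W(k−1).  This stabilised the selection decisively in simulations
(without it, occasional k* = 10–11 selections occurred at the candidate
range edge).

### Two-level procedure

Each subject's GFP-peak maps are clustered for every candidate k and the
subject's class count k*_i is selected by KL.  The subjects' normalised
cluster-mean topographies are then pooled and clustered again with a
constraint: at every sweep, each subject's templates must map to
min(k*_i, k) *distinct* group classes.  The constrained assignment is
solved per subject as a rectangular linear assignment problem
(`scipy.optimize.linear_sum_assignment`) maximising total |correlation|;
when a subject has more templates than there are classes, each class
first receives its best-matched template and the remainder fall to their
individual best class.  Group templates are dominant eigenvectors of
their member templates; k* is selected by KL on the pooled dispersion
curve.  The pipeline also reports the per-group selections so agreement
between patient-only, control-only, and pooled selections can be checked.

Group classes are labeled after the canonical microstate topographies
A–E by a one-to-one assignment against schematic reference maps rendered
on the montage (two diagonal gradients, a frontal-central pattern, a
fronto-occipital pattern, a centro-parietal pattern); surplus classes
continue F, G, … in descending explained-variance order.

## Back-fitting, segmentation, features

Group templates are fitted back competitively: each GFP-peak map (or
each unmasked frame in the every-timeframe variant) takes the class with
the highest |spatial correlation|, ties broken toward the lowest class
index.  Runs of equally-labeled consecutive peaks merge into one
microstate whose boundaries are the midpoints (in continuous time, not
rounded to samples) to the neighbouring differently-labeled peaks.  The
first and last run of every usable stretch lack one boundary and are
excluded from analysis, as are runs bordering masked gaps.

In the every-timeframe variant the label sequence contains brief
flickers at GFP troughs, where the momentary map is mostly noise; label
runs shorter than 20 ms are therefore reassigned to the
better-correlated neighbouring state (the standard small-segment
rejection used in frame-wise microstate segmentation; configurable, 0
disables).  Peak-based segmentation needs no such step because peaks are
the high-SNR samples by construction.

Per class and subject, three features are computed from the valid
segments: mean duration (ms), frequency of occurrence (segments per
second), and proportional coverage time (%).  The denominator for
occurrence and coverage is the total time inside valid segments, which
keeps the three features mutually consistent and coverage summing to
100% exactly; the raw usable recording length is available behind
`denominator="usable"`.

## Group statistics

- **Cohen's d** uses the pooled-SD formula, signed patients minus
  controls.
- **TANOVA**: subject mean maps per class (peak maps sign-aligned to the
  class template, then averaged) are normalised to unit GFP; the
  statistic is the GFP of the difference between group-mean maps; the
  p-value is `(1 + #{perm ≥ obs}) / (1 + n_perm)` over random relabelings
  (default 4999, seedable).  Subject maps are sorted canonically before
  permuting so the p-value cannot depend on listing order.
- **Electrode-wise t-tests** compare normalised absolute voltages per
  electrode between groups (follow-up for classes flagged by TANOVA).
- **Mixed models**: `feature ~ class * group + age + sex` with a Gaussian
  random intercept per subject, ML fit (REML behind a flag), Wald z for
  the per-class group contrast (group main effect + interaction).  A
  boundary fit (random-intercept variance 0) is reported in a `singular`
  column and falls back to the equivalent OLS when the mixed solver
  fails outright.
- **Dirichlet regression** for coverage (compositional): common
  parameterisation α_jc = exp(x_jᵀβ_c) with covariates intercept, group,
  standardised age, sex.  The likelihood is maximised by damped Newton
  ascent on the analytic gradient and observed information
  (Levenberg–Marquardt damping, backtracking on the exact log-likelihood,
  so accepted steps are monotone).  Wald z comes from the inverse
  observed information.  Boundary zeros are nudged by 1e-6 and the
  composition renormalised.  With very small cohorts the MLE can diverge
  (a binary covariate subgroup fit perfectly sends its precision to
  infinity — the Dirichlet analogue of separation); this is detected via
  the gradient norm and reported, never silently truncated.
- **Familywise error**: 3k* effects are examined but coverage is
  determined by duration and occurrence, so the threshold is
  0.05 / (2k*) (0.005 at k* = 5).

## Synthetic cohorts

The generator emulates eyes-closed resting EEG with planted microstate
structure:

- **Montage**: quasi-uniform Fibonacci layout on the upper unit
  hemisphere; 64 channels by default (204 supported), 250 Hz, 300 s.
- **State sequence**: semi-Markov chain; dwell times gamma with shape 2
  (positive, right-skewed, consistent with reported mean±SD magnitudes)
  and per-class/group means; successors drawn from occurrence weights
  excluding self-transitions.  Group defaults use the dwell means and
  occurrence rates reported for insomnia patients versus controls
  (C dwell 52.7 vs 60.7 ms; D propensity 4.45 vs 3.80), so the planted
  contrast is "shorter C, busier D" in patients.
- **Between-subject variability**: per-subject, per-class dwell means and
  occurrence weights are scaled by mean-one lognormal factors with CV
  0.18.  This reproduces realistic between-subject spreads (duration SD
  ≈ 7–17 ms, coverage SD ≈ 3–10 points); without it the cohort is so
  homogeneous that mixed-model random intercepts collapse and Dirichlet
  precisions diverge.
- **Rendering**: `signal(t) = s_seg · T_subj[label(t)] · env(t) · A` with
  env(t) = 0.5 + 0.5·|sin(2πft + φ)| (10 Hz carrier → ~20 GFP peaks/s),
  per-dwell-segment random polarity s_seg (exercising polarity invariance
  downstream), and per-subject template jitter 0.1.  The envelope floor
  keeps some topographic signal at the carrier's polarity reversals:
  real GFP dips between peaks but never vanishes, and a hard null makes
  every between-peak frame pure noise, contradicting the observed
  near-equivalence of peak-wise and frame-wise feature extraction.
- **Noise**: Gaussian, spatially correlated over the montage (squared-
  exponential kernel, length scale twice the median nearest-neighbour
  electrode distance), band-limited 1–40 Hz, scaled so the RMS-GFP ratio
  of state signal to noise equals `snr` (default 4).  White noise would
  make the clustering unrealistically easy.
- **Masks**: two 2-s unusable segments by default, exercising the
  edge-omission rules.
- **Ground truth**: per subject, the planted (jittered) templates, the
  sample-level state sequence, and features obtained by directly counting
  that sequence — so downstream extraction can be checked exactly.

What the generator does **not** emulate: volume-conducted dipolar
forward fields, 1/f background spectra, eye/muscle artifacts beyond
masked gaps, eyes-open data, non-stationary vigilance drift, or real
GEV levels (synthetic GEV at GFP peaks is ~90% at snr 4 versus ~66%
reported for real recordings).  Passing tests therefore demonstrate the
correctness and statistical behaviour of the pipeline under a controlled
model, not performance on real recordings.

## Problem sizes in the tests and acceptance script

Simulation-based checks run at reduced sizes chosen to keep the suite
quick while leaving the conclusions stable: cohorts of 8–20 subjects
with 40–240 s recordings and 6–10 k-means restarts (defaults are 20
restarts and 300-s recordings).  The class-count replication study uses
ten cohorts of 8 subjects x 40 s; the peak-versus-frame equivalence uses
16 subjects at 240 s (between-subject correlations need the per-subject
feature estimates to be stable, which takes minutes of data);
calibration suites use 500 simulated feature tables (mixed model) and
1000 permutation-test replicates (TANOVA); the acceptance script runs
ten cohorts of 16 subjects x 60 s with 10 restarts.

## Known limitations

- The KL criterion remains a heuristic; on dispersion curves without an
  elbow it returns the formula's argmax, which is documented but not
  meaningful.
- The constrained group assignment with more subject templates than
  group classes uses a cover-then-argmax heuristic rather than an exact
  constrained optimum (the exact problem is a degree-constrained
  assignment; the heuristic is exact whenever k*_i ≤ k, which is the
  typical regime).
- Dispersion descent of the modified k-means is monotone in practice and
  enforced via best-state tracking, but the eigenvector update optimises
  Σ corr² rather than Σ|corr|, so per-sweep monotonicity in the reported
  dispersion is not a theorem.
- Wald tests are asymptotic: with 32 subjects per group the mixed-model
  per-class type-I error sits near 0.06 at nominal 0.05 (measured in the
  calibration suite), consistent with z versus t critical values.
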