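"""Synthetic two-group EEG cohorts with planted microstate structure.

The generator emulates the regime of eyes-closed resting recordings:
~10 Hz oscillatory activity whose momentary topography dwells in one of a
small set of quasi-stable classes for tens of milliseconds at a time.  A
semi-Markov chain draws the class sequence (gamma dwell times, class- and
group-specific means in the 50-65 ms range; next class drawn from
class-propensity weights excluding self-transitions).  The scalp signal is
the active class template modulated by a rectified 10 Hz carrier, with the
template's polarity flipped at random per dwell segment, plus spatially
correlated band-limited noise.  Because every quantity is planted, each
downstream stage can be checked against an exact ground truth.

Defaults mirror a two-group insomnia/control study design: 32 subjects
per group, 250 Hz sampling, 5 classes, and per-class dwell means and
occurrence propensities in the ranges reported for such cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .montage import Montage, make_montage
from .signal_prep import Recording, mask_from_intervals
from .clustering import normalize_maps, abs_spatial_corr

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_templates",
    "canonical_references",
    "simulate_state_sequence",
    "render_eeg",
    "simulate_cohort",
    "true_features",
]

GROUPS = ("control", "patient")

# per-class dwell-time means (ms) and relative occurrence propensities;
# class order A, B, C, D, E.  The planted group contrast: patients have a
# shorter class-C dwell and a higher class-D propensity.
DEFAULT_DURATION_MEANS = {
    "control": (53.9, 57.6, 60.7, 60.4, 50.5),
    "patient": (51.5, 53.5, 52.7, 62.7, 47.3),
}
DEFAULT_OCCURRENCE_WEIGHTS = {
    "control": (3.42, 3.71, 3.67, 3.80, 3.07),
    "patient": (3.64, 3.89, 3.51, 4.45, 3.02),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``duration_means`` and ``occurrence_weights`` map group name to a
    per-class tuple; dwell times are gamma distributed with the given mean
    (ms) and fixed shape.  ``snr`` is the ratio of the state signal's
    root-mean-square GFP to the noise's.  ``template_jitter`` (0-1)
    perturbs each subject's templates away from the planted group
    templates before rendering.
    """

    n_per_group: int = 32
    n_channels: int = 64
    sampling_rate: float = 250.0
    duration: float = 300.0
    n_classes: int = 5
    carrier_freq: float = 10.0
    # relative amplitude at the carrier's polarity reversals: real GFP
    # dips between peaks but never to zero, and a hard null would make
    # every between-peak frame pure noise
    carrier_floor: float = 0.5
    duration_means: dict = field(default_factory=lambda: {
        g: DEFAULT_DURATION_MEANS[g] for g in GROUPS})
    dwell_shape: float = 2.0
    occurrence_weights: dict = field(default_factory=lambda: {
        g: DEFAULT_OCCURRENCE_WEIGHTS[g] for g in GROUPS})
    snr: float = 4.0
    template_jitter: float = 0.1
    between_subject_cv: float = 0.18  # lognormal CV of per-subject rates
    amplitude: float = 10.0  # microvolts, peak template scale
    n_mask_segments: int = 2
    mask_segment_duration: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (self-transitions are "
                             "excluded, so a single class cannot switch)")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer "
                             "sample count")
        for g in GROUPS:
            means = np.asarray(self.duration_means[g], dtype=float)
            w = np.asarray(self.occurrence_weights[g], dtype=float)
            if means.size != self.n_classes or w.size != self.n_classes:
                raise ValueError(
                    "duration_means and occurrence_weights must have one "
                    "entry per class")
            if np.any(means <= 0):
                raise ValueError("dwell-time means must be positive")
            if np.any(w <= 0):
                raise ValueError("occurrence weights must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["duration_means"] = {g: list(v) for g, v in d["duration_means"].items()}
        d["occurrence_weights"] = {
            g: list(v) for g, v in d["occurrence_weights"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("duration_means", "occurrence_weights"):
            if key in d:
                d[key] = {g: tuple(v) for g, v in d[key].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything planted for one subject."""

    subject: str
    group: str
    templates: np.ndarray          # (n_classes, n_channels) planted, unit GFP
    state_sequence: np.ndarray     # (n_samples,) class index per sample
    features: pd.DataFrame         # class x (mean_duration_ms, occurrence, coverage)


def _schematic_patterns(montage: Montage) -> np.ndarray:
    """Five canonical-style patterns on a montage (rows; not normalised).

    Two diagonal gradients (left/right occipital-to-frontal), a
    frontal-central pattern, a fronto-occipital dipole, and a
    centro-parietal pattern, built as smooth functions of electrode
    position (x right, y anterior, z up).
    """
    p = montage.positions

    def blob(center, width=0.8):
        c = np.asarray(center, dtype=float)
        c = c / np.linalg.norm(c)
        d2 = np.sum((p - c) ** 2, axis=1)
        return np.exp(-d2 / (2 * width ** 2))

    s2 = np.sqrt(2.0)
    patterns = np.vstack([
        (p[:, 0] + p[:, 1]) / s2,                      # A: L-occ to R-front
        (-p[:, 0] + p[:, 1]) / s2,                     # B: R-occ to L-front
        blob((0.0, 0.55, 0.85), 0.45),                 # C: frontal-central
        blob((0.0, 0.9, 0.45), 0.40)
        - blob((0.0, -0.9, 0.45), 0.40),               # D: fronto-occipital
        blob((0.0, -0.25, 0.97), 0.45),                # E: centro-parietal
    ])
    return patterns


def canonical_references(montage: Montage) -> np.ndarray:
    """Schematic canonical class maps A-E on a montage, unit GFP.

    These stand in for the published canonical microstate topographies
    when labeling group classes; they capture the configuration (gradient
    orientation, anterior-posterior structure), not exact voltages.
    """
    return normalize_maps(_schematic_patterns(montage))


def _spatial_chol(montage: Montage) -> np.ndarray:
    """Cholesky factor of a squared-exponential kernel over electrodes.

    Length scale = twice the median nearest-neighbour electrode distance,
    so noise is correlated across neighbouring sensors as real EEG noise
    is, which keeps the clustering problem honestly hard.
    """
    d = montage.pairwise_distances()
    nearest = np.partition(d + np.eye(d.shape[0]) * 10, 1, axis=1)[:, 1]
    length_scale = float(np.median(nearest)) * 2.0
    k = np.exp(-d ** 2 / (2 * length_scale ** 2))
    return np.linalg.cholesky(k + 1e-8 * np.eye(k.shape[0]))


def _smooth_channel_noise(montage: Montage, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated Gaussian channel patterns (n, n_channels)."""
    chol = _spatial_chol(montage)
    white = rng.standard_normal((n, chol.shape[0]))
    return white @ chol.T


def make_templates(
    montage: Montage,
    n_classes: int = 5,
    seed: int | np.random.Generator = 0,
    max_corr: float = 0.7,
    max_attempts: int = 50,
    perturbation: float = 0.15,
) -> np.ndarray:
    """Planted class templates: average-referenced, unit-GFP scalp maps.

    The first five classes are perturbed versions of the schematic
    canonical patterns; further classes are random smooth maps.  Pairwise
    absolute spatial correlations are required to stay at or below
    ``max_corr`` so the classes are genuinely distinct; generation retries
    with fresh perturbations and raises after ``max_attempts`` failures.
    """
    if montage.n_scalp < n_classes:
        raise ValueError("montage has fewer channels than classes")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = _schematic_patterns(montage)
    base = normalize_maps(base)
    for _ in range(max_attempts):
        rows = []
        for c in range(n_classes):
            if c < base.shape[0]:
                raw = base[c]
            else:
                raw = _smooth_channel_noise(montage, 1, rng)[0]
            noise = _smooth_channel_noise(montage, 1, rng)[0]
            noise = noise / np.sqrt(np.mean(noise ** 2))
            rows.append(raw + perturbation * noise)
        templates = normalize_maps(np.vstack(rows))
        ok = True
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                if abs_spatial_corr(templates[i], templates[j]) > max_corr:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return templates
    raise ValueError(
        f"could not draw {n_classes} templates with pairwise |corr| <= "
        f"{max_corr} on this montage after {max_attempts} attempts")


def subject_rates(config: SimulationConfig, group: str,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject dwell means (ms) and occurrence weights.

    Individuals differ: the group-level values are scaled per class by a
    mean-one lognormal factor with coefficient of variation
    ``between_subject_cv``, which reproduces the between-subject spread
    seen in real cohorts (duration SDs around 7-17 ms, coverage SDs of a
    few percentage points).
    """
    means_ms = np.asarray(config.duration_means[group], dtype=float)
    weights = np.asarray(config.occurrence_weights[group], dtype=float)
    cv = config.between_subject_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv ** 2))
        means_ms = means_ms * rng.lognormal(-sigma ** 2 / 2, sigma,
                                            means_ms.size)
        weights = weights * rng.lognormal(-sigma ** 2 / 2, sigma,
                                          weights.size)
    return means_ms, weights


def simulate_state_sequence(
    config: SimulationConfig,
    group: str,
    rng: int | np.random.Generator,
    dwell_means_ms: np.ndarray | None = None,
    occurrence_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Sample-indexed class labels from the semi-Markov switching model.

    Dwell times are gamma with per-class/group mean (ms) and common shape;
    the successor class is drawn from the group's occurrence weights with
    the current class excluded.  Passing explicit ``dwell_means_ms`` /
    ``occurrence_weights`` overrides the group-level values (used for
    per-subject variability).
    """
    if group not in config.duration_means:
        raise ValueError(f"unknown group {group!r}")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    n = config.n_samples
    fs = config.sampling_rate
    means_ms = (np.asarray(dwell_means_ms, dtype=float)
                if dwell_means_ms is not None
                else np.asarray(config.duration_means[group], dtype=float))
    weights = (np.asarray(occurrence_weights, dtype=float)
               if occurrence_weights is not None
               else np.asarray(config.occurrence_weights[group], dtype=float))
    if np.any(means_ms <= 0) or np.any(weights <= 0):
        raise ValueError("dwell means and weights must be positive")
    shape = config.dwell_shape
    labels = np.empty(n, dtype=np.int64)
    current = int(rng.choice(config.n_classes, p=weights / weights.sum()))
    t = 0
    while t < n:
        dwell_ms = rng.gamma(shape, means_ms[current] / shape)
        dwell = max(1, int(round(dwell_ms / 1000.0 * fs)))
        labels[t:t + dwell] = current
        t += dwell
        w = weights.copy()
        w[current] = 0.0
        current = int(rng.choice(config.n_classes, p=w / w.sum()))
    return labels


def true_features(state_sequence: np.ndarray, sampling_rate: float,
                  n_classes: int) -> pd.DataFrame:
    """Dynamic features by direct counting on a label sequence.

    Mean duration (ms) over a class's dwell segments, occurrence
    (segments per second of sequence), and coverage (percent of samples).
    """
    labels = np.asarray(state_sequence)
    n = labels.size
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    seg_labels = labels[starts]
    seg_len = ends - starts
    total_s = n / sampling_rate
    rows = []
    for c in range(n_classes):
        sel = seg_labels == c
        n_seg = int(sel.sum())
        mean_ms = (float(seg_len[sel].mean()) / sampling_rate * 1000.0
                   if n_seg else np.nan)
        rows.append({
            "class_index": c,
            "mean_duration_ms": mean_ms,
            "occurrence_per_s": n_seg / total_s,
            "coverage_pct": 100.0 * float(seg_len[sel].sum()) / n,
        })
    return pd.DataFrame(rows)


def render_eeg(
    state_sequence: np.ndarray,
    templates: np.ndarray,
    config: SimulationConfig,
    rng: int | np.random.Generator,
    montage: Montage | None = None,
    subject: str = "S0",
    group: str = "control",
) -> tuple[Recording, GroundTruth]:
    """Render a label sequence into multichannel EEG plus its ground truth.

    ``signal(t) = s_seg * T_subj[label(t)] * env(t) * A`` with the
    rectified-carrier envelope ``env(t) = floor + (1 - floor) *
    |sin(2 pi f t + phi)|``, per-dwell-segment random polarity ``s_seg``
    and per-subject jittered templates, plus spatially smoothed
    band-limited noise scaled to the configured GFP signal-to-noise
    ratio.  The floor keeps some topographic signal at the carrier's
    polarity reversals, as in real recordings where the global field
    power dips between its peaks but never vanishes.  The output is
    average-referenced, with optional masked segments inserted.
    """
    from scipy import signal as sps

    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    if montage is None:
        montage = make_montage(config.n_channels)
    templates = normalize_maps(templates)
    if templates.shape[1] != montage.n_scalp:
        raise ValueError("templates do not match montage")
    labels = np.asarray(state_sequence)
    n = labels.size
    fs = config.sampling_rate

    # per-subject template perturbation, then renormalise
    if config.template_jitter > 0:
        pert = _smooth_channel_noise(montage, templates.shape[0], rng)
        pert = pert / np.sqrt(np.mean(pert ** 2, axis=1, keepdims=True))
        subj_templates = normalize_maps(
            templates + config.template_jitter * pert)
    else:
        subj_templates = templates.copy()

    t = np.arange(n) / fs
    phi = rng.uniform(0, 2 * np.pi)
    floor = config.carrier_floor
    envelope = (floor + (1 - floor)
                * np.abs(np.sin(2 * np.pi * config.carrier_freq * t + phi)))

    # random polarity per dwell segment
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    seg_sign = rng.choice([-1.0, 1.0], size=starts.size)
    sign = np.repeat(seg_sign, np.diff(np.concatenate([starts, [n]])))

    signal = (subj_templates[labels].T * (envelope * sign)[None, :]
              * config.amplitude)

    if np.isfinite(config.snr):
        white = rng.standard_normal((montage.n_scalp, n))
        noise = _spatial_chol(montage) @ white
        if 40.0 < fs / 2:
            sos = sps.butter(4, [1.0, 40.0], btype="bandpass", fs=fs,
                             output="sos")
            noise = sps.sosfiltfilt(sos, noise, axis=1)
        noise = noise - noise.mean(axis=0, keepdims=True)
        sig_gfp = np.sqrt(np.mean(signal ** 2))
        noise_gfp = np.sqrt(np.mean(noise ** 2))
        noise *= sig_gfp / (config.snr * noise_gfp)
        data = signal + noise
    else:
        data = signal
    data = data - data.mean(axis=0, keepdims=True)

    mask = np.ones(n, dtype=bool)
    if config.n_mask_segments > 0 and config.mask_segment_duration > 0:
        seg_s = config.mask_segment_duration
        total_s = n / fs
        if config.n_mask_segments * seg_s < 0.5 * total_s:
            starts_s = rng.uniform(0.05 * total_s, 0.95 * total_s - seg_s,
                                   size=config.n_mask_segments)
            mask = mask_from_intervals(
                [(s, s + seg_s) for s in starts_s], n, fs)

    rec = Recording(subject=subject, group=group, sampling_rate=fs,
                    data=data, mask=mask, montage=montage)
    truth = GroundTruth(
        subject=subject, group=group, templates=subj_templates,
        state_sequence=labels,
        features=true_features(labels, fs, templates.shape[0]),
    )
    return rec, truth


def simulate_cohort(
    config: SimulationConfig,
    montage: Montage | None = None,
) -> tuple[list[Recording], list[GroundTruth], pd.DataFrame]:
    """Generate the full two-group cohort.

    Returns recordings, per-subject ground truths, and a sample sheet with
    subject id, group, age, and sex covariates.  Fully deterministic given
    ``config.seed``.
    """
    if montage is None:
        montage = make_montage(config.n_channels)
    root = np.random.SeedSequence(config.seed)
    template_rng = np.random.default_rng(root.spawn(1)[0])
    templates = make_templates(montage, config.n_classes, template_rng)
    recordings: list[Recording] = []
    truths: list[GroundTruth] = []
    rows = []
    idx = 0
    for group in GROUPS:
        for i in range(config.n_per_group):
            subject = f"{'C' if group == 'control' else 'P'}{i + 1:03d}"
            sub_rng = np.random.default_rng(root.spawn(1)[0])
            means_ms, weights = subject_rates(config, group, sub_rng)
            seq = simulate_state_sequence(config, group, sub_rng,
                                          dwell_means_ms=means_ms,
                                          occurrence_weights=weights)
            rec, truth = render_eeg(seq, templates, config, sub_rng,
                                    montage=montage, subject=subject,
                                    group=group)
            recordings.append(rec)
            truths.append(truth)
            rows.append({
                "subject": subject,
                "group": group,
                "age": float(np.round(sub_rng.uniform(21, 70), 1)),
                "sex": "F" if sub_rng.random() < 0.8 else "M",
            })
            idx += 1
    sheet = pd.DataFrame(rows)
    return recordings, truths, sheet
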