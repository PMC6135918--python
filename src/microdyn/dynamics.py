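"""Back-fitting of group templates, segmentation, and dynamic features.

Once group-level class templates exist, each recording is labeled
competitively: every GFP-peak topography (or every frame, in the
every-timeframe variant) goes to the class with the highest absolute
spatial correlation.  Runs of equal labels become microstate segments
whose boundaries are the midpoints to the neighbouring GFP peaks; the
first and last segment of each usable stretch have an unestimable
boundary and are excluded.  From the valid segments come the three
standard dynamic features per class: mean duration (ms), frequency of
occurrence (1/s), and proportional coverage time (%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_prep import Recording, compute_gfp, find_gfp_peaks, unmasked_runs
from .clustering import GroupMicrostateModel, normalize_maps, _corr_matrix

__all__ = [
    "MicrostateSegment",
    "MicrostateSequence",
    "backfit",
    "segment",
    "segment_frames",
    "features",
    "feature_table",
    "peak_vs_frame_equivalence",
]

FEATURES = ("mean_duration_ms", "occurrence_per_s", "coverage_pct")


@dataclass
class MicrostateSegment:
    label: int
    start: float  # seconds
    end: float
    valid: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MicrostateSequence:
    subject: str
    segments: list
    total_usable_time: float  # seconds

    @property
    def valid_segments(self) -> list:
        return [s for s in self.segments if s.valid]


def _competitive_labels(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """argmax-|corr| class per map; ties go to the lowest class index."""
    corr = np.abs(_corr_matrix(maps, templates))
    return np.argmax(corr, axis=1)


def backfit(
    recording: Recording,
    group_model: GroupMicrostateModel | np.ndarray,
    at_peaks_only: bool = True,
    min_segment_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Competitively assign class templates to a recording.

    Returns ``(labels, indices)``: with ``at_peaks_only`` the indices are
    the GFP peak samples and labels align with them; otherwise indices are
    all sample positions and labels has one entry per sample, with masked
    samples labeled -1.  Zero-variance frames inherit the previous frame's
    label; a leading zero-variance run is left unlabeled (-1).

    Frame-wise labeling applies the standard small-segment rejection:
    label runs shorter than ``min_segment_ms`` (low-GFP flickers between
    peaks) are reassigned to the better-correlated neighbouring state,
    since a topographic state cannot plausibly last a couple of samples.
    Set ``min_segment_ms=0`` to disable.
    """
    templates = (group_model.templates
                 if isinstance(group_model, GroupMicrostateModel)
                 else np.asarray(group_model))
    templates = normalize_maps(templates)
    if templates.shape[1] != recording.n_channels:
        raise ValueError("model channels do not match recording")
    gfp_series = compute_gfp(recording)
    if at_peaks_only:
        peaks = find_gfp_peaks(gfp_series, recording.mask)
        if peaks.size == 0:
            return np.array([], dtype=int), peaks
        maps = normalize_maps(recording.data[:, peaks].T)
        return _competitive_labels(maps, templates), peaks

    labels = np.full(recording.n_samples, -1, dtype=int)
    corr_abs = np.zeros((recording.n_samples, templates.shape[0]))
    gfp = gfp_series.gfp
    min_samples = int(round(min_segment_ms / 1000.0
                            * recording.sampling_rate))
    for start, stop in unmasked_runs(recording.mask):
        seg_gfp = gfp[start:stop]
        nonzero = seg_gfp > 0
        if np.any(nonzero):
            idx = np.flatnonzero(nonzero) + start
            maps = normalize_maps(recording.data[:, idx].T)
            corr = np.abs(_corr_matrix(maps, templates))
            corr_abs[idx] = corr
            labels[idx] = np.argmax(corr, axis=1)
        # zero-variance frames copy the previous label within the run
        for t in range(start, stop):
            if labels[t] == -1 and t > start and labels[t - 1] != -1:
                labels[t] = labels[t - 1]
        if min_samples > 1:
            labels[start:stop] = _reject_small_segments(
                labels[start:stop], corr_abs[start:stop], min_samples)
    return labels, np.arange(recording.n_samples)


def _reject_small_segments(labels: np.ndarray, corr_abs: np.ndarray,
                           min_samples: int, max_sweeps: int = 20
                           ) -> np.ndarray:
    """Merge label runs shorter than ``min_samples`` into a neighbour.

    Each short run is relabeled as a whole to whichever adjacent run's
    class correlates better with its frames (mean absolute spatial
    correlation).  Sweeps repeat until no short run remains or the
    structure stops changing.
    """
    labels = labels.copy()
    n = labels.size
    for _ in range(max_sweeps):
        breaks = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [n]])
        lengths = ends - starts
        short = np.flatnonzero(lengths < min_samples)
        # the first and last run border the stretch edge; leave them if
        # they have no inner neighbour to merge into
        changed = False
        for r in short:
            if labels[starts[r]] < 0:
                continue
            candidates = []
            if r > 0 and labels[starts[r - 1]] >= 0:
                candidates.append(labels[starts[r - 1]])
            if r < starts.size - 1 and labels[starts[r + 1]] >= 0:
                candidates.append(labels[starts[r + 1]])
            if not candidates:
                continue
            frames = slice(starts[r], ends[r])
            best = max(candidates,
                       key=lambda c: corr_abs[frames, c].mean())
            if best != labels[starts[r]]:
                labels[frames] = best
                changed = True
        if not changed:
            break
    return labels


def segment(
    labels: np.ndarray,
    peak_indices: np.ndarray,
    mask: np.ndarray,
    sampling_rate: float,
    subject: str = "",
) -> MicrostateSequence:
    """Merge equal-labeled consecutive GFP peaks into microstate segments.

    Within each usable stretch, a run of consecutive peaks sharing a label
    becomes one segment reaching from the midpoint between the previous
    run's last peak and this run's first peak, to the midpoint between
    this run's last peak and the next run's first peak (midpoints in
    continuous time).  The first and last run of every stretch lack one
    boundary and are marked invalid, as are runs of unlabeled peaks.
    Stretches with fewer than three peaks yield no valid segments.
    """
    labels = np.asarray(labels)
    peak_indices = np.asarray(peak_indices)
    mask = np.asarray(mask, dtype=bool)
    segments: list[MicrostateSegment] = []
    for start, stop in unmasked_runs(mask):
        sel = (peak_indices >= start) & (peak_indices < stop)
        p = peak_indices[sel]
        l = labels[sel]
        if p.size == 0:
            continue
        run_breaks = np.flatnonzero(np.diff(l)) + 1
        run_starts = np.concatenate([[0], run_breaks])
        run_ends = np.concatenate([run_breaks, [l.size]])  # exclusive
        n_runs = run_starts.size
        for r in range(n_runs):
            first, last = p[run_starts[r]], p[run_ends[r] - 1]
            interior = 0 < r < n_runs - 1
            if interior:
                prev_last = p[run_starts[r] - 1]
                next_first = p[run_ends[r]]
                t0 = (prev_last + first) / 2.0 / sampling_rate
                t1 = (last + next_first) / 2.0 / sampling_rate
            else:
                t0 = first / sampling_rate
                t1 = (last + 1) / sampling_rate
            valid = interior and l[run_starts[r]] >= 0
            segments.append(MicrostateSegment(
                label=int(l[run_starts[r]]), start=float(t0), end=float(t1),
                valid=bool(valid)))
    total_usable = float(mask.sum()) / sampling_rate
    return MicrostateSequence(subject=subject, segments=segments,
                              total_usable_time=total_usable)


def segment_frames(
    frame_labels: np.ndarray,
    mask: np.ndarray,
    sampling_rate: float,
    subject: str = "",
) -> MicrostateSequence:
    """Segments from an every-timeframe labeling.

    Runs of equal labels within a usable stretch become segments spanning
    their sample extent; the first and last run of each stretch border an
    unestimable boundary and are invalid, mirroring the peak-based rule.
    """
    frame_labels = np.asarray(frame_labels)
    mask = np.asarray(mask, dtype=bool)
    segments: list[MicrostateSegment] = []
    for start, stop in unmasked_runs(mask):
        l = frame_labels[start:stop]
        if l.size == 0:
            continue
        run_breaks = np.flatnonzero(np.diff(l)) + 1
        run_starts = np.concatenate([[0], run_breaks])
        run_ends = np.concatenate([run_breaks, [l.size]])
        n_runs = run_starts.size
        for r in range(n_runs):
            t0 = (start + run_starts[r]) / sampling_rate
            t1 = (start + run_ends[r]) / sampling_rate
            valid = (0 < r < n_runs - 1) and l[run_starts[r]] >= 0
            segments.append(MicrostateSegment(
                label=int(l[run_starts[r]]), start=float(t0), end=float(t1),
                valid=bool(valid)))
    total_usable = float(mask.sum()) / sampling_rate
    return MicrostateSequence(subject=subject, segments=segments,
                              total_usable_time=total_usable)


def features(
    sequence: MicrostateSequence,
    k_star: int,
    denominator: str = "valid",
) -> pd.DataFrame:
    """Per-class dynamic features from the valid segments of one subject.

    mean_duration_ms: mean length of the class's valid segments;
    occurrence_per_s: count of valid segments over the total time in valid
    segments (or total usable time with ``denominator="usable"``);
    coverage_pct: percent of that same denominator spent in the class.
    Classes without segments get occurrence 0, coverage 0, and a missing
    mean duration.
    """
    valid = sequence.valid_segments
    if not valid:
        raise ValueError("sequence has no valid segments")
    if denominator not in ("valid", "usable"):
        raise ValueError("denominator must be 'valid' or 'usable'")
    total = (sum(s.duration for s in valid) if denominator == "valid"
             else sequence.total_usable_time)
    rows = []
    for c in range(k_star):
        segs = [s for s in valid if s.label == c]
        dur = [s.duration for s in segs]
        rows.append({
            "class_index": c,
            "mean_duration_ms": (float(np.mean(dur)) * 1000.0 if dur
                                 else np.nan),
            "occurrence_per_s": len(segs) / total,
            "coverage_pct": 100.0 * sum(dur) / total,
        })
    return pd.DataFrame(rows)


def feature_table(
    recordings,
    group_model: GroupMicrostateModel,
    sample_sheet: pd.DataFrame | None = None,
    at_peaks_only: bool = True,
    denominator: str = "valid",
) -> pd.DataFrame:
    """Subject x class feature grid for a whole cohort.

    One row per subject per class with the three dynamic features, plus
    group/age/sex covariates when a sample sheet is supplied.
    """
    frames = []
    for rec in recordings:
        if at_peaks_only:
            labels, peaks = backfit(rec, group_model, at_peaks_only=True)
            seq = segment(labels, peaks, rec.mask, rec.sampling_rate,
                          subject=rec.subject)
        else:
            labels, _ = backfit(rec, group_model, at_peaks_only=False)
            seq = segment_frames(labels, rec.mask, rec.sampling_rate,
                                 subject=rec.subject)
        f = features(seq, group_model.k_star, denominator=denominator)
        f.insert(0, "subject", rec.subject)
        f.insert(1, "group", rec.group)
        if group_model.canonical_labels:
            f["class"] = [group_model.canonical_labels[c]
                          for c in f["class_index"]]
        else:
            f["class"] = f["class_index"].astype(str)
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    if sample_sheet is not None:
        table = table.merge(sample_sheet[["subject", "age", "sex"]],
                            on="subject", how="left")
    return table


def peak_vs_frame_equivalence(
    table_peaks: pd.DataFrame, table_frames: pd.DataFrame
) -> pd.DataFrame:
    """Across-subject Pearson r between the two back-fitting variants.

    One row per class x feature comparing the feature values obtained by
    fitting at GFP peaks only versus at every timeframe.
    """
    rows = []
    for cls in sorted(table_peaks["class_index"].unique()):
        a = table_peaks[table_peaks["class_index"] == cls].set_index("subject")
        b = table_frames[table_frames["class_index"] == cls].set_index("subject")
        common = a.index.intersection(b.index)
        for feat in FEATURES:
            x = a.loc[common, feat].to_numpy(float)
            y = b.loc[common, feat].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"class_index": cls, "feature": feat, "r": r})
    return pd.DataFrame(rows)
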