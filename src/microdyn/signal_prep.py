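"""Final-stage conditioning of cleaned EEG and GFP peak extraction.

This stage assumes the heavy artifact cleaning (drift removal, channel
rejection/interpolation, independent-component cleaning) has already
happened upstream; it applies the 1-40 Hz band-pass, the common average
reference, and locates the local maxima of the global field power (GFP)
within the usable (unmasked) portions of the recording.  The topographies
at those maxima are the atoms of microstate clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .montage import Montage

__all__ = [
    "Recording",
    "GfpSeries",
    "bandpass_and_reref",
    "compute_gfp",
    "find_gfp_peaks",
    "mask_from_intervals",
    "intervals_from_mask",
    "unmasked_runs",
]


@dataclass
class Recording:
    """One subject's multichannel EEG.

    Attributes
    ----------
    subject : str
    group : str
        Group label, e.g. ``"control"`` or ``"patient"``.
    sampling_rate : float
        Hz.
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    mask : ndarray of bool, shape (n_samples,)
        True where the sample is usable.
    montage : Montage
    """

    subject: str
    group: str
    sampling_rate: float
    data: np.ndarray
    mask: np.ndarray
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape[0] != self.data.shape[1]:
            raise ValueError("mask length must equal sample count")
        if self.montage is not None and self.data.shape[0] not in (
            self.montage.n_channels,
            self.montage.n_scalp,
        ):
            raise ValueError("channel count does not match montage")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GfpSeries:
    """Global field power over time with detected peak indices."""

    gfp: np.ndarray
    peak_indices: np.ndarray
    sampling_rate: float


def _select_scalp(recording: Recording) -> Recording:
    """Drop non-scalp channels (cheek/nape) if any remain."""
    mont = recording.montage
    if mont is None or recording.n_channels == mont.n_scalp:
        return recording
    idx = np.flatnonzero(mont.scalp)
    return replace(
        recording, data=recording.data[idx], montage=mont.scalp_subset()
    )


def bandpass_and_reref(
    recording: Recording, low: float = 1.0, high: float = 40.0
) -> Recording:
    """Zero-phase band-pass filter and common-average re-reference.

    The filter is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``), so peak latencies are preserved.  After filtering,
    every sample is re-expressed relative to the instantaneous mean over
    scalp channels, so each output frame has channel mean zero.  The mask
    is carried through unchanged.

    Raises
    ------
    ValueError
        If the band falls outside (0, Nyquist).
    """
    fs = recording.sampling_rate
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={fs / 2}) Hz"
        )
    rec = _select_scalp(recording)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return replace(rec, data=filtered)


def compute_gfp(recording: Recording, atol: float = 1e-6) -> GfpSeries:
    """Global field power: spatial standard deviation of each frame.

    ``gfp(t) = sqrt(mean_i v_i(t)^2)`` for the average-referenced frame
    ``v``.  The input must already be average-referenced (channel mean 0
    at every sample, within ``atol`` relative to the frame's scale).
    """
    v = recording.data
    means = v.mean(axis=0)
    scale = max(np.abs(v).max(), 1.0)
    if np.abs(means).max() > atol * scale:
        raise ValueError("recording is not average-referenced")
    gfp = np.sqrt(np.mean(v ** 2, axis=0))
    return GfpSeries(gfp=gfp, peak_indices=np.array([], dtype=int),
                     sampling_rate=recording.sampling_rate)


def unmasked_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive usable samples."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, edges.size, 2)]


def find_gfp_peaks(gfp_series: GfpSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Indices of strict local GFP maxima inside usable runs.

    A peak is a sample ``t`` with ``gfp(t-1) < gfp(t) > gfp(t+1)`` and both
    neighbours unmasked; samples at the edges of a usable run cannot be
    peaks.  Flat maxima take the first sample of the plateau.
    """
    g = np.asarray(gfp_series.gfp, dtype=float)
    if mask is None:
        mask = np.ones(g.size, dtype=bool)
    peaks: list[int] = []
    for start, stop in unmasked_runs(mask):
        seg = g[start:stop]
        if seg.size < 3:
            continue
        mid = seg[1:-1]
        strict = np.flatnonzero((mid > seg[:-2]) & (mid > seg[2:])) + 1
        peaks.extend(start + t for t in strict)
        # flat maxima: first sample of the plateau counts
        flat_start = np.flatnonzero((mid > seg[:-2]) & (mid == seg[2:])) + 1
        for t in flat_start:
            u = t
            while u + 1 < seg.size and seg[u + 1] == seg[t]:
                u += 1
            if u + 1 < seg.size and seg[u + 1] < seg[t]:
                peaks.append(start + t)
    return np.asarray(sorted(peaks), dtype=int)


def mask_from_intervals(
    intervals, n_samples: int, sampling_rate: float
) -> np.ndarray:
    """Boolean usable-mask from half-open bad intervals in seconds.

    ``intervals`` is an iterable of ``(start_s, end_s)`` pairs marking
    unusable stretches; time origin 0 at the first sample.
    """
    mask = np.ones(n_samples, dtype=bool)
    for start_s, end_s in intervals:
        if end_s <= start_s:
            raise ValueError("interval end must exceed start")
        a = int(np.floor(start_s * sampling_rate))
        b = int(np.ceil(end_s * sampling_rate))
        mask[max(a, 0):min(b, n_samples)] = False
    return mask


def intervals_from_mask(mask: np.ndarray, sampling_rate: float):
    """Inverse of :func:`mask_from_intervals`: bad stretches in seconds."""
    bad = ~np.asarray(mask, dtype=bool)
    out = []
    for start, stop in unmasked_runs(bad):
        out.append((start / sampling_rate, stop / sampling_rate))
    return out
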