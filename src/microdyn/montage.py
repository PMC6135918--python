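"""Electrode montages: positions on the unit sphere plus a scalp subset flag.

A montage is the geometric side of every scalp map: channel identifiers,
3-D sensor positions normalised to the unit sphere, and a boolean marking
which channels lie over the scalp proper (as opposed to cheek/nape channels
that are excluded from topographic analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Montage", "make_montage", "load_montage", "save_montage"]


@dataclass(frozen=True)
class Montage:
    """Sensor layout on the unit sphere.

    Parameters
    ----------
    ids : list of str
        Unique channel identifiers.
    positions : ndarray, shape (n_channels, 3)
        Unit vectors; ``|position| = 1`` within 1e-6.
    scalp : ndarray of bool, shape (n_channels,)
        True for channels used in topographic analysis.
    """

    ids: tuple
    positions: np.ndarray
    scalp: np.ndarray = field(default=None)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("channel ids must be unique")
        if len(self.ids) != pos.shape[0]:
            raise ValueError("ids and positions length mismatch")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must be unit vectors (|p| = 1 ± 1e-6)")
        object.__setattr__(self, "positions", pos)
        scalp = self.scalp
        if scalp is None:
            scalp = np.ones(pos.shape[0], dtype=bool)
        scalp = np.asarray(scalp, dtype=bool)
        if scalp.shape[0] != pos.shape[0]:
            raise ValueError("scalp flag length mismatch")
        object.__setattr__(self, "scalp", scalp)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n_channels(self) -> int:
        return len(self.ids)

    @property
    def n_scalp(self) -> int:
        return int(self.scalp.sum())

    def scalp_subset(self) -> "Montage":
        """Montage restricted to the scalp channels."""
        idx = np.flatnonzero(self.scalp)
        return Montage(
            ids=tuple(self.ids[i] for i in idx),
            positions=self.positions[idx],
            scalp=np.ones(idx.size, dtype=bool),
        )

    def pairwise_distances(self) -> np.ndarray:
        """Euclidean (chord) distances between electrode positions."""
        p = self.positions
        d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
        return np.sqrt(np.maximum(d2, 0.0))


def make_montage(n_channels: int = 64, n_nonscalp: int = 0) -> Montage:
    """Quasi-uniform electrode layout on the upper unit hemisphere.

    Uses a Fibonacci lattice restricted to z >= 0 (head apex at +z), which
    spreads ``n_channels`` sensors nearly evenly over the scalp dome.  With
    ``n_nonscalp > 0``, that many additional channels are placed on the rim
    (z slightly below 0, emulating cheek/nape sensors) and flagged as
    non-scalp.

    Deterministic: same arguments always give the same montage.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 scalp channels")
    golden = (1 + 5 ** 0.5) / 2
    # sample 2*n points over the full sphere, keep the upper half
    m = 2 * n_channels + 1
    i = np.arange(m)
    z = 1 - 2 * (i + 0.5) / m
    theta = 2 * np.pi * i / golden
    upper = z >= 0
    z = z[upper][:n_channels]
    theta = theta[upper][:n_channels]
    if z.size < n_channels:
        raise ValueError("could not place requested channel count")
    r = np.sqrt(np.maximum(1 - z ** 2, 0.0))
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    ids = [f"E{k + 1}" for k in range(n_channels)]
    scalp = [True] * n_channels
    if n_nonscalp:
        phi = 2 * np.pi * np.arange(n_nonscalp) / n_nonscalp
        zr = -0.15
        rr = np.sqrt(1 - zr ** 2)
        rim = np.column_stack(
            [rr * np.cos(phi), rr * np.sin(phi), np.full(n_nonscalp, zr)]
        )
        pos = np.vstack([pos, rim])
        ids += [f"X{k + 1}" for k in range(n_nonscalp)]
        scalp += [False] * n_nonscalp
    return Montage(ids=tuple(ids), positions=pos, scalp=np.array(scalp))


def save_montage(montage: Montage, path) -> None:
    """Write a montage as delimited text: id, x, y, z, scalp flag."""
    df = pd.DataFrame(
        {
            "id": list(montage.ids),
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
            "scalp": montage.scalp.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_montage(path) -> Montage:
    """Read a montage from delimited text (id, x, y, z, scalp)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "x", "y", "z", "scalp"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file must have columns {sorted(required)}")
    pos = df[["x", "y", "z"]].to_numpy(float)
    # renormalise against round-tripping error
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(
        ids=tuple(str(s) for s in df["id"]),
        positions=pos,
        scalp=df["scalp"].to_numpy(bool),
    )
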