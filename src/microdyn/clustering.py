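"""Polarity-invariant topographic clustering of GFP-peak maps.

Microstate analysis treats a scalp map and its sign-flip as the same brain
state, so all comparisons here use the absolute spatial (Pearson)
correlation between maps.  Clustering proceeds in two levels: a modified
k-means per subject over that subject's GFP-peak topographies, then a
constrained k-means over all subjects' per-cluster mean topographies, with
the number of classes selected at both levels by the Krzanowski-Lai
criterion on the dispersion curve.

Conventions used throughout: maps are rows of shape (n_maps, n_channels),
average-referenced (each row sums to zero) and normalised to unit global
field power, so the spatial correlation between two maps reduces to their
dot product divided by the channel count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .signal_prep import Recording, compute_gfp, find_gfp_peaks

__all__ = [
    "abs_spatial_corr",
    "normalize_maps",
    "modified_kmeans",
    "krzanowski_lai_select",
    "SubjectClusterModel",
    "GroupMicrostateModel",
    "cluster_subject",
    "cluster_group",
    "canonical_labeling",
    "global_explained_variance",
]

CANDIDATE_RANGE = (3, 11)  # classes considered by the selection criterion


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and scale each row to unit global field power.

    Raises on rows with zero spatial variance, which carry no topography.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    centered = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(centered ** 2, axis=1))
    if np.any(gfp == 0):
        raise ValueError("zero-variance map cannot be normalised")
    return centered / gfp[:, None]


def abs_spatial_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute spatial correlation between two scalp maps, in [0, 1].

    The Pearson correlation across channels, with polarity ignored by
    taking the absolute value: a map and its sign-flip correlate at 1.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map has undefined correlation")
    return float(abs(uc @ vc) / (nu * nv))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed spatial correlations; rows maps, columns templates.

    Assumes both inputs are centered rows of unit GFP, so correlation is
    the dot product over the channel count.
    """
    return (maps @ templates.T) / maps.shape[1]


def _dominant_eigvec(members: np.ndarray, v0: np.ndarray,
                     tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Dominant eigenvector of the outer-product sum of ``members``.

    Power iteration on the (implicit) positive semi-definite matrix
    ``members.T @ members``, warm-started at ``v0``; never forms the
    channels-by-channels matrix.  Returns a unit-norm vector.
    """
    v = v0 / np.linalg.norm(v0)
    for _ in range(max_iter):
        w = members.T @ (members @ v)
        nw = np.linalg.norm(w)
        if nw == 0:  # v orthogonal to row space; restart from first member
            v = members[0] / np.linalg.norm(members[0])
            continue
        w /= nw
        if np.linalg.norm(w - v) < tol:
            return w
        v = w
    return v


def _unit_gfp(v: np.ndarray) -> np.ndarray:
    return v / np.sqrt(np.mean(v ** 2))


def _kmeans_single(maps: np.ndarray, templates: np.ndarray, k: int,
                   max_iter: int, squared: bool = False):
    """One k-means run from given starting templates.

    Returns the best state seen across sweeps (dispersion is evaluated
    after every assignment), plus the dispersion history.
    """
    n = maps.shape[0]
    templates = templates.copy()
    labels = np.full(n, -1, dtype=int)
    history: list[float] = []
    best = None
    for _ in range(max_iter):
        abs_corr = np.abs(_corr_matrix(maps, templates))
        new_labels = np.argmax(abs_corr, axis=1)
        # reseed empty clusters from the worst-fitted maps (distinct ones)
        fit = abs_corr[np.arange(n), new_labels]
        empty = [j for j in range(k) if not np.any(new_labels == j)]
        if empty:
            for j, worst in zip(empty, np.argsort(fit)):
                templates[j] = maps[worst]
                new_labels[worst] = j
                fit[worst] = 1.0
        dispersion = float(np.sum(1.0 - fit ** 2) if squared
                           else np.sum(1.0 - fit))
        history.append(dispersion)
        if best is None or dispersion < best[2]:
            best = (templates.copy(), new_labels.copy(), dispersion)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = maps[labels == j]
            if members.shape[0]:
                templates[j] = _unit_gfp(
                    _dominant_eigvec(members, templates[j]))
    return best[0], best[1], best[2], history


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    n_restarts: int = 20,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    return_history: bool = False,
    extra_inits: list[np.ndarray] | None = None,
    dispersion: str = "abs_corr",
):
    """Polarity-invariant k-means over normalised scalp maps.

    Each map is assigned to the template with maximal absolute spatial
    correlation; each template is then recomputed as the dominant
    eigenvector of the outer-product sum of its assigned maps (the
    polarity-invariant centroid).  Iterations stop when the assignment no
    longer changes or after ``max_iter`` sweeps.  The best of
    ``n_restarts`` random initialisations (plus any ``extra_inits``
    starting templates) by minimal dispersion is kept.

    Returns
    -------
    templates : ndarray (k, n_channels), unit GFP
    labels : ndarray (n_maps,)
    dispersion : float
        ``sum(1 - |corr(map, assigned template)|)`` over all maps, or
        ``sum(1 - corr^2)`` with ``dispersion="squared"`` (an alternative
        within-cluster dissimilarity; the assignment rule is identical).
    history : list of float, optional
        Dispersion after each assignment sweep of the winning restart
        (``return_history=True`` only).
    """
    maps = normalize_maps(maps)
    n, c = maps.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of maps ({n})")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # tiny instances: enumerate every distinct k-subset of maps as an
    # initialisation instead of sampling (restart sampling can miss the
    # globally optimal basin when only a handful of subsets exist)
    if math.comb(n, k) <= max(4 * n_restarts, 64):
        inits = [maps[list(c)] for c in itertools.combinations(range(n), k)]
    else:
        inits = [maps[rng.choice(n, size=k, replace=False)]
                 for _ in range(n_restarts)]
    for t0 in (extra_inits or []):
        if t0.shape != (k, c):
            raise ValueError("extra init has wrong shape")
        inits.append(normalize_maps(t0))
    if dispersion not in ("abs_corr", "squared"):
        raise ValueError("dispersion must be 'abs_corr' or 'squared'")
    squared = dispersion == "squared"
    best = None
    for t0 in inits:
        templates, labels, disp_val, history = _kmeans_single(
            maps, t0, k, max_iter, squared=squared)
        if best is None or disp_val < best[2]:
            best = (templates, labels, disp_val, history)
    templates, labels, dispersion, history = best
    if return_history:
        return templates, labels, dispersion, history
    return templates, labels, dispersion


def _incremental_init(maps: np.ndarray, prev_templates: np.ndarray
                      ) -> np.ndarray:
    """Previous solution extended by the worst-fitted map as a new class.

    Used as one extra initialisation when sweeping k upward: its starting
    dispersion is at most the previous k's final dispersion, which keeps
    the dispersion curve non-increasing in k.
    """
    abs_corr = np.abs(_corr_matrix(maps, prev_templates))
    worst = int(np.argmin(abs_corr.max(axis=1)))
    return np.vstack([prev_templates, maps[worst][None, :]])


def krzanowski_lai_select(
    W_by_k: dict[int, float],
    n_channels: int,
    k_range: tuple[int, int] = CANDIDATE_RANGE,
) -> tuple[int, dict[int, float]]:
    """Cluster-count selection by maximal normalised curvature.

    With dispersion ``W(k)`` and data dimensionality ``p`` (the number of
    scalp channels), ``DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k)`` and
    ``KL(k) = |DIFF(k)| / |DIFF(k+1)|``; the selected count maximises
    ``KL(k)`` over the candidate range.  Requires ``W`` at ``k_min - 1``
    through ``k_max + 1``.

    Returns the selected ``k`` and the ``KL`` value per candidate.
    """
    k_min, k_max = k_range
    p = float(n_channels)
    needed = range(k_min - 1, k_max + 2)
    missing = [k for k in needed if k not in W_by_k]
    if missing:
        raise ValueError(f"W missing for k={missing}")

    def diff(k: int) -> float:
        return ((k - 1) ** (2.0 / p)) * W_by_k[k - 1] - (k ** (2.0 / p)) * W_by_k[k]

    kl: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        denom = abs(diff(k + 1))
        if denom == 0:
            continue  # criterion undefined at this k
        kl[k] = abs(diff(k)) / denom
    if not kl:
        raise ValueError("KL criterion undefined at every candidate k")
    k_selected = max(kl, key=lambda k: (kl[k], -k))
    return k_selected, kl


@dataclass
class SubjectClusterModel:
    """Per-subject clustering result across candidate class counts."""

    subject: str
    W_by_k: dict[int, float]
    KL_by_k: dict[int, float]
    k_star: int
    templates: np.ndarray  # (k_star, n_channels), unit GFP
    labels: np.ndarray | None = None  # assignment of GFP-peak maps
    n_peaks: int = 0


@dataclass
class GroupMicrostateModel:
    """Group-level microstate classes shared across subjects."""

    k_star: int
    templates: np.ndarray  # (k_star, n_channels), unit GFP
    canonical_labels: list[str] = field(default_factory=list)
    assignment: dict[str, np.ndarray] = field(default_factory=dict)
    W_by_k: dict[int, float] = field(default_factory=dict)
    KL_by_k: dict[int, float] = field(default_factory=dict)
    gev_per_subject: dict[str, float] = field(default_factory=dict)

    def label_of(self, class_index: int) -> str:
        if self.canonical_labels:
            return self.canonical_labels[class_index]
        return str(class_index)


def peak_maps(recording: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Normalised topographies at the GFP local maxima of a recording."""
    gfp = compute_gfp(recording)
    peaks = find_gfp_peaks(gfp, recording.mask)
    maps = recording.data[:, peaks].T
    return normalize_maps(maps) if peaks.size else maps, peaks


def cluster_subject(
    recording: Recording,
    candidate_range: tuple[int, int] = CANDIDATE_RANGE,
    seed: int = 0,
    n_restarts: int = 20,
    min_peaks: int | None = None,
) -> SubjectClusterModel:
    """Cluster one subject's GFP-peak maps and select the class count.

    The modified k-means runs for every ``k`` from one below to one above
    the candidate range (the selection criterion needs the flanking
    dispersions), and the Krzanowski-Lai criterion picks ``k_star``.
    """
    k_min, k_max = candidate_range
    maps, peaks = peak_maps(recording)
    if min_peaks is None:
        min_peaks = 12 * k_max
    if peaks.size < min_peaks:
        raise ValueError(
            f"subject {recording.subject}: {peaks.size} GFP peaks found, "
            f"at least {min_peaks} required for clustering over "
            f"k={k_min}..{k_max}"
        )
    rng = np.random.default_rng(seed)
    W: dict[int, float] = {}
    tmpl: dict[int, np.ndarray] = {}
    lbl: dict[int, np.ndarray] = {}
    norm_maps = normalize_maps(maps)
    prev = None
    for k in range(k_min - 1, k_max + 2):
        extra = ([_incremental_init(norm_maps, prev)]
                 if prev is not None else None)
        t, l, w = modified_kmeans(maps, k, n_restarts=n_restarts, seed=rng,
                                  extra_inits=extra)
        W[k], tmpl[k], lbl[k] = w, t, l
        prev = t
    k_star, kl = krzanowski_lai_select(W, maps.shape[1], candidate_range)
    return SubjectClusterModel(
        subject=recording.subject,
        W_by_k=W,
        KL_by_k=kl,
        k_star=k_star,
        templates=tmpl[k_star],
        labels=lbl[k_star],
        n_peaks=int(peaks.size),
    )


def _constrained_assign(
    corr_abs: np.ndarray, k: int
) -> np.ndarray:
    """Assign one subject's templates to distinct group classes.

    ``corr_abs`` is (n_subject_templates, k).  When the subject has at
    most ``k`` templates, an optimal one-to-one assignment maximising the
    total correlation is used.  With more templates than classes, each
    class first receives its best-matched template (so min(ki, k) distinct
    classes are hit) and the remaining templates fall to their individual
    best class.
    """
    ki = corr_abs.shape[0]
    assign = np.empty(ki, dtype=int)
    if ki <= k:
        rows, cols = linear_sum_assignment(-corr_abs)
        assign[rows] = cols
    else:
        rows, cols = linear_sum_assignment(-corr_abs.T)  # class -> template
        assign[:] = np.argmax(corr_abs, axis=1)
        assign[cols] = rows
    return assign


def cluster_group(
    subject_models: list[SubjectClusterModel],
    candidate_range: tuple[int, int] = CANDIDATE_RANGE,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 100,
) -> GroupMicrostateModel:
    """Constrained group-level clustering of subjects' template maps.

    All subjects' normalised cluster-mean topographies are pooled and
    clustered for each candidate ``k``; at every assignment sweep each
    subject's templates are mapped to ``min(ki, k)`` *distinct* group
    classes by an optimal one-to-one assignment on absolute spatial
    correlation.  Group templates are dominant eigenvectors of their
    members; ``k_star`` is selected by the Krzanowski-Lai criterion.
    """
    if len(subject_models) < 2:
        raise ValueError("need at least 2 subject models")
    k_min, k_max = candidate_range
    pooled = np.vstack([normalize_maps(m.templates) for m in subject_models])
    subj_slices = []
    start = 0
    for m in subject_models:
        ki = m.templates.shape[0]
        subj_slices.append((start, start + ki))
        start += ki
    n, c = pooled.shape
    rng = np.random.default_rng(seed)

    def run_once(k: int, init_templates: np.ndarray | None = None):
        if init_templates is None:
            init = rng.choice(n, size=min(k, n), replace=False)
            templates = pooled[init].copy()
        else:
            templates = init_templates.copy()
        labels = np.full(n, -1, dtype=int)
        best = None
        for _ in range(max_iter):
            corr_abs = np.abs(_corr_matrix(pooled, templates))
            new_labels = np.empty(n, dtype=int)
            for (a, b) in subj_slices:
                new_labels[a:b] = _constrained_assign(corr_abs[a:b], k)
            fit = corr_abs[np.arange(n), new_labels]
            empty = [j for j in range(k) if not np.any(new_labels == j)]
            if empty:
                for j, worst in zip(empty, np.argsort(fit)):
                    templates[j] = pooled[worst]
                    new_labels[worst] = j
                    fit[worst] = 1.0
            dispersion = float(np.sum(1.0 - fit))
            if best is None or dispersion < best[2]:
                best = (templates.copy(), new_labels.copy(), dispersion)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = pooled[labels == j]
                if members.shape[0]:
                    templates[j] = _unit_gfp(
                        _dominant_eigvec(members, templates[j]))
        return best

    W: dict[int, float] = {}
    tmpl: dict[int, np.ndarray] = {}
    lbl: dict[int, np.ndarray] = {}
    prev = None
    for k in range(k_min - 1, k_max + 2):
        if k >= n:
            # more classes than pooled maps: every map its own class,
            # zero dispersion (KL excludes these k via the zero DIFF rule)
            tmpl[k], lbl[k], W[k] = pooled.copy(), np.arange(n), 0.0
            prev = None
            continue
        best = None
        for _ in range(n_restarts):
            t, l, w = run_once(k)
            if best is None or w < best[2]:
                best = (t, l, w)
        if prev is not None:
            t, l, w = run_once(k, _incremental_init(pooled, prev))
            if w < best[2]:
                best = (t, l, w)
        tmpl[k], lbl[k], W[k] = best
        prev = tmpl[k]
    k_star, kl = krzanowski_lai_select(W, c, candidate_range)
    assignment = {
        m.subject: lbl[k_star][a:b]
        for m, (a, b) in zip(subject_models, subj_slices)
    }
    return GroupMicrostateModel(
        k_star=k_star,
        templates=tmpl[k_star],
        assignment=assignment,
        W_by_k=W,
        KL_by_k=kl,
    )


def canonical_labeling(
    group_model: GroupMicrostateModel,
    reference_templates: np.ndarray,
    reference_labels: list[str] | None = None,
    ev_per_class: np.ndarray | None = None,
) -> GroupMicrostateModel:
    """Label group classes after the canonical microstate topographies.

    Each group template is matched one-to-one to the reference maps
    (canonical classes A-E rendered on the same montage) so that the total
    absolute spatial correlation is maximal; polarity is ignored.  Group
    templates left without a reference (k_star beyond the reference count)
    are labeled F, G, ... in order of decreasing explained variance when
    ``ev_per_class`` is given, otherwise by class index.
    """
    refs = normalize_maps(reference_templates)
    if reference_labels is None:
        reference_labels = [chr(ord("A") + i) for i in range(refs.shape[0])]
    templates = normalize_maps(group_model.templates)
    corr_abs = np.abs(_corr_matrix(templates, refs))
    rows, cols = linear_sum_assignment(-corr_abs)
    labels: list[str | None] = [None] * templates.shape[0]
    for r, ccol in zip(rows, cols):
        labels[r] = reference_labels[ccol]
    surplus = [i for i, s in enumerate(labels) if s is None]
    if surplus:
        if ev_per_class is not None:
            surplus.sort(key=lambda i: -float(ev_per_class[i]))
        extra = [chr(ord("A") + len(reference_labels) + j)
                 for j in range(len(surplus))]
        for i, name in zip(surplus, extra):
            labels[i] = name
    group_model.canonical_labels = list(labels)
    return group_model


def global_explained_variance(
    recording: Recording,
    group_model: GroupMicrostateModel,
    labels_at_peaks: np.ndarray | None = None,
) -> float:
    """GFP-weighted percentage of topographic variance the model explains.

    ``GEV = 100 * sum_t (gfp_t * corr(v_t, T_label(t)))^2 / sum_t gfp_t^2``
    over the GFP peaks ``t``, where ``v_t`` is the momentary map and
    ``T_label(t)`` its competitively assigned template.
    """
    gfp_series = compute_gfp(recording)
    peaks = find_gfp_peaks(gfp_series, recording.mask)
    if peaks.size == 0:
        raise ValueError("no GFP peaks to evaluate")
    gfp = gfp_series.gfp[peaks]
    if np.sum(gfp ** 2) == 0:
        raise ValueError("zero total GFP power")
    maps = normalize_maps(recording.data[:, peaks].T)
    templates = normalize_maps(group_model.templates)
    corr = _corr_matrix(maps, templates)
    if labels_at_peaks is None:
        labels_at_peaks = np.argmax(np.abs(corr), axis=1)
    chosen = corr[np.arange(peaks.size), labels_at_peaks]
    gev = 100.0 * float(np.sum((gfp * chosen) ** 2) / np.sum(gfp ** 2))
    return gev
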