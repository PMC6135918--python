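"""End-to-end analysis: conditioning, clustering, back-fit, features, stats.

`run_pipeline` strings the stages together in the canonical order:
band-pass + average reference, GFP-peak extraction and per-subject
clustering, constrained group clustering with class-count selection,
canonical labeling, competitive back-fitting and segmentation, the three
dynamic features, and the two-group statistics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_prep import Recording, bandpass_and_reref
from .clustering import (
    CANDIDATE_RANGE,
    GroupMicrostateModel,
    cluster_group,
    cluster_subject,
    canonical_labeling,
    global_explained_variance,
    normalize_maps,
    _corr_matrix,
)
from .dynamics import FEATURES, backfit, feature_table
from .synthetic import canonical_references
from . import stats as gstats

__all__ = ["PipelineResult", "run_pipeline", "subject_mean_maps",
           "summarize_features"]


@dataclass
class PipelineResult:
    subject_models: list
    group_model: GroupMicrostateModel
    features: pd.DataFrame
    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    tanova: pd.DataFrame = field(default_factory=pd.DataFrame)
    electrode_tests: dict = field(default_factory=dict)
    fwer_threshold: float = np.nan
    kl_agreement: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)


def subject_mean_maps(
    recordings: list[Recording], group_model: GroupMicrostateModel
) -> dict[int, pd.DataFrame]:
    """Per-subject mean topography of each class's assigned peak maps.

    Peak maps are normalised, sign-aligned to the class template (polarity
    is a nuisance), and averaged.  Returns, per class index, a frame with
    one row per subject holding the subject id, group, and the mean map.
    """
    templates = normalize_maps(group_model.templates)
    out: dict[int, list] = {c: [] for c in range(group_model.k_star)}
    for rec in recordings:
        labels, peaks = backfit(rec, group_model, at_peaks_only=True)
        if peaks.size == 0:
            continue
        maps = normalize_maps(rec.data[:, peaks].T)
        corr = _corr_matrix(maps, templates)
        for c in range(group_model.k_star):
            sel = labels == c
            if not np.any(sel):
                continue
            signs = np.sign(corr[sel, c])
            signs[signs == 0] = 1.0
            mean_map = (maps[sel] * signs[:, None]).mean(axis=0)
            out[c].append((rec.subject, rec.group, mean_map))
    frames = {}
    for c, rows in out.items():
        frames[c] = pd.DataFrame(
            {"subject": [r[0] for r in rows],
             "group": [r[1] for r in rows],
             "map": [r[2] for r in rows]})
    return frames


def summarize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD and pooled-SD Cohen's d per class x feature."""
    rows = []
    for (cls, cname), sub in features.groupby(["class_index", "class"]):
        for feat in FEATURES:
            g1 = sub.loc[sub["group"] == "control", feat].dropna()
            g2 = sub.loc[sub["group"] == "patient", feat].dropna()
            d = np.nan
            if len(g1) >= 2 and len(g2) >= 2:
                try:
                    d = gstats.cohens_d(g1.mean(), g1.std(ddof=1), len(g1),
                                        g2.mean(), g2.std(ddof=1), len(g2))
                except ValueError:
                    pass
            rows.append({
                "class_index": cls, "class": cname, "feature": feat,
                "control_mean": g1.mean(), "control_sd": g1.std(ddof=1),
                "patient_mean": g2.mean(), "patient_sd": g2.std(ddof=1),
                "cohens_d": d,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    recordings: list[Recording],
    sample_sheet: pd.DataFrame | None = None,
    band: tuple[float, float] = (1.0, 40.0),
    candidate_range: tuple[int, int] = CANDIDATE_RANGE,
    seed: int = 0,
    n_restarts: int = 20,
    n_perm: int = 4999,
    at_peaks_only: bool = True,
    denominator: str = "valid",
    min_peaks: int | None = None,
    run_stats: bool = True,
    kl_per_group: bool = True,
) -> PipelineResult:
    """Run the full microstate analysis on a cohort of recordings."""
    timings = {}
    t0 = time.perf_counter()
    conditioned = [bandpass_and_reref(r, *band) for r in recordings]
    timings["signal_prep"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rng = np.random.default_rng(seed)
    subject_models = []
    for rec in conditioned:
        subject_models.append(cluster_subject(
            rec, candidate_range, seed=int(rng.integers(2 ** 31)),
            n_restarts=n_restarts, min_peaks=min_peaks))
    timings["subject_clustering"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    group_model = cluster_group(
        subject_models, candidate_range,
        seed=int(rng.integers(2 ** 31)), n_restarts=n_restarts)
    kl_agreement = {"pooled": group_model.k_star}
    if kl_per_group and sample_sheet is not None:
        by_subject = dict(zip(sample_sheet["subject"], sample_sheet["group"]))
        for gname in sorted(set(by_subject.values())):
            models_g = [m for m in subject_models
                        if by_subject.get(m.subject) == gname]
            if len(models_g) >= 2:
                gm = cluster_group(models_g, candidate_range,
                                   seed=int(rng.integers(2 ** 31)),
                                   n_restarts=n_restarts)
                kl_agreement[gname] = gm.k_star
    timings["group_clustering"] = time.perf_counter() - t0

    refs = canonical_references(conditioned[0].montage)
    group_model = canonical_labeling(group_model, refs)
    for rec in conditioned:
        group_model.gev_per_subject[rec.subject] = (
            global_explained_variance(rec, group_model))

    t0 = time.perf_counter()
    table = feature_table(conditioned, group_model, sample_sheet,
                          at_peaks_only=at_peaks_only,
                          denominator=denominator)
    timings["features"] = time.perf_counter() - t0

    result = PipelineResult(
        subject_models=subject_models,
        group_model=group_model,
        features=table,
        kl_agreement=kl_agreement,
        timings=timings,
    )
    if not run_stats:
        return result

    t0 = time.perf_counter()
    if sample_sheet is not None:
        n_groups = table.groupby("group")["subject"].nunique()
        if len(n_groups) < 2 or n_groups.min() < 2:
            raise ValueError("statistics need at least 2 subjects per group")
    effects = []
    for feat, func in (("mean_duration_ms", gstats.lmm_contrasts),
                       ("occurrence_per_s", gstats.lmm_contrasts)):
        eff = func(table, feat)
        eff["feature"] = feat
        effects.append(eff)
    try:
        dfit = gstats.dirichlet_regression(table)
        dcon = dfit.contrasts.copy()
        dcon["converged"] = dfit.converged
    except RuntimeError as exc:
        # diverging precisions (separation on a small cohort): report the
        # failure in the results instead of losing the remaining stats
        dcon = pd.DataFrame({
            "class_index": sorted(table["class_index"].unique()),
            "estimate": np.nan, "se": np.nan, "z": np.nan, "p": np.nan,
            "converged": False, "error": str(exc),
        })
    dcon["feature"] = "coverage_pct"
    effects.append(dcon)
    effects = pd.concat(effects, ignore_index=True)

    mean_maps = subject_mean_maps(conditioned, group_model)
    tan_rows = []
    for c in range(group_model.k_star):
        frame = mean_maps[c]
        a = np.vstack(frame.loc[frame["group"] == "control", "map"])
        b = np.vstack(frame.loc[frame["group"] == "patient", "map"])
        p, stat = gstats.tanova(a, b, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)))
        tan_rows.append({"class_index": c,
                         "class": group_model.label_of(c),
                         "statistic": stat, "p": p})
        if p < 0.05:  # follow-up: where on the scalp does the class differ
            t_map, p_map = gstats.electrodewise_t(a, b)
            result.electrode_tests[c] = {"t": t_map, "p": p_map}
    threshold, n_tests = gstats.fwer_threshold(group_model.k_star)
    result.effects = effects
    result.tanova = pd.DataFrame(tan_rows)
    result.fwer_threshold = threshold
    timings["stats"] = time.perf_counter() - t0
    result.timings = timings
    return result
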