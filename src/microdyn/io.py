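"""On-disk formats: delimited recordings, sample sheets, models, manifests.

Everything is inspectable text: recordings as delimited sample-by-channel
matrices (EDF is read through mne when it is installed), montages and
tables as TSV, models / ground truth / manifests as JSON, configuration
as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage, load_montage, save_montage
from .signal_prep import Recording, mask_from_intervals, intervals_from_mask
from .clustering import GroupMicrostateModel
from .synthetic import GroundTruth, SimulationConfig, true_features

__all__ = [
    "write_recording", "read_recording", "read_edf",
    "write_sample_sheet", "read_sample_sheet",
    "write_ground_truth", "read_ground_truth",
    "write_group_model", "read_group_model",
    "write_mask_intervals", "read_mask_intervals",
    "load_config", "save_config",
    "write_cohort",
]


def write_recording(rec: Recording, path) -> None:
    """Recording as TSV: one row per sample, one column per channel."""
    ids = rec.montage.ids if rec.montage is not None else [
        f"ch{i}" for i in range(rec.n_channels)]
    df = pd.DataFrame(rec.data.T, columns=list(ids)[:rec.n_channels])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_recording(
    path, montage: Montage, sampling_rate: float,
    subject: str = "", group: str = "", mask: np.ndarray | None = None,
) -> Recording:
    df = pd.read_csv(path, sep="\t")
    data = df.to_numpy(float).T
    return Recording(subject=subject, group=group,
                     sampling_rate=sampling_rate, data=data,
                     mask=mask, montage=montage)


def read_edf(path, subject: str = "", group: str = "",
             montage: Montage | None = None) -> Recording:
    """Read an EDF recording through mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(subject=subject, group=group,
                     sampling_rate=float(raw.info["sfreq"]), data=data,
                     mask=None, montage=montage)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"subject", "file", "group", "age", "sex"}
    missing = required - set(sheet.columns)
    if missing - {"file"}:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["subject"].duplicated().any():
        raise ValueError("duplicate subject ids in sample sheet")
    return sheet


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    payload = []
    for t in truths:
        payload.append({
            "subject": t.subject,
            "group": t.group,
            "templates": np.round(t.templates, 10).tolist(),
            "state_sequence": t.state_sequence.astype(int).tolist(),
            "features": t.features.round(10).to_dict(orient="records"),
        })
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path, sampling_rate: float) -> list[GroundTruth]:
    payload = json.loads(Path(path).read_text())
    out = []
    for t in payload:
        seq = np.asarray(t["state_sequence"], dtype=int)
        templates = np.asarray(t["templates"], dtype=float)
        out.append(GroundTruth(
            subject=t["subject"], group=t["group"], templates=templates,
            state_sequence=seq,
            features=pd.DataFrame(t["features"]),
        ))
    return out


def write_group_model(model: GroupMicrostateModel, path) -> None:
    payload = {
        "k_star": model.k_star,
        "templates": np.asarray(model.templates).tolist(),
        "canonical_labels": model.canonical_labels,
        "assignment": {s: np.asarray(a).astype(int).tolist()
                       for s, a in model.assignment.items()},
        "W_by_k": {str(k): v for k, v in model.W_by_k.items()},
        "KL_by_k": {str(k): v for k, v in model.KL_by_k.items()},
        "gev_per_subject": model.gev_per_subject,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_group_model(path) -> GroupMicrostateModel:
    d = json.loads(Path(path).read_text())
    return GroupMicrostateModel(
        k_star=int(d["k_star"]),
        templates=np.asarray(d["templates"], dtype=float),
        canonical_labels=list(d.get("canonical_labels", [])),
        assignment={s: np.asarray(a, dtype=int)
                    for s, a in d.get("assignment", {}).items()},
        W_by_k={int(k): float(v) for k, v in d.get("W_by_k", {}).items()},
        KL_by_k={int(k): float(v) for k, v in d.get("KL_by_k", {}).items()},
        gev_per_subject=d.get("gev_per_subject", {}),
    )


def write_mask_intervals(mask: np.ndarray, sampling_rate: float, path) -> None:
    """Bad stretches as half-open [start, end) second intervals, TSV."""
    rows = intervals_from_mask(mask, sampling_rate)
    pd.DataFrame(rows, columns=["start_s", "end_s"]).to_csv(
        path, sep="\t", index=False)


def read_mask_intervals(path, n_samples: int, sampling_rate: float) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return mask_from_intervals(
        df[["start_s", "end_s"]].to_numpy(float), n_samples, sampling_rate)


def load_config(path) -> SimulationConfig:
    """Simulation configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()))


def write_cohort(
    recordings, truths, sheet: pd.DataFrame, out_dir,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Write a simulated cohort: recordings, montage, masks, sheet, truth.

    Returns the sample sheet augmented with file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = recordings[0].montage
    save_montage(montage, out / "montage.tsv")
    files = []
    for rec in recordings:
        fname = f"{rec.subject}.tsv"
        write_recording(rec, out / fname)
        write_mask_intervals(rec.mask, rec.sampling_rate,
                             out / f"{rec.subject}_mask.tsv")
        files.append(fname)
    sheet = sheet.copy()
    sheet.insert(1, "file", files)
    write_sample_sheet(sheet, out / "sample_sheet.tsv")
    write_ground_truth(truths, out / "ground_truth.json")
    if config is not None:
        save_config(config, out / "config.yaml")
    return sheet
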