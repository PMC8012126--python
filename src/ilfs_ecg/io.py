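"""Plain-text I/O: recordings as CSV + JSON sidecar, tabular data as CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset_builder import TrialRating
from .hrv_features import FEATURE_NAMES
from .preprocess import EcgRecording
from .rpeak import RRSeries
from .synthetic_data import GroundTruth, TrialTruth


def write_recording(rec: EcgRecording, out_dir: str | Path) -> Path:
    """Write one recording as ``<subject>.csv`` (single sample column) plus a
    ``<subject>.json`` sidecar carrying fs and the trial-onset events."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{rec.subject_id}.csv"
    np.savetxt(csv_path, rec.samples, fmt="%.6f", header="ecg_mv", comments="")
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "events": [{"trial_id": t, "onset_s": o} for t, o in rec.events],
    }
    (out_dir / f"{rec.subject_id}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path) -> EcgRecording:
    csv_path = Path(csv_path)
    samples = np.loadtxt(csv_path, skiprows=1)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    events = [(e["trial_id"], float(e["onset_s"])) for e in meta["events"]]
    return EcgRecording(samples, float(meta["fs"]), events, meta["subject_id"])


def write_ratings(ratings: list[TrialRating], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in ratings]).to_csv(path, index=False)


def read_ratings(path: str | Path) -> list[TrialRating]:
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    return [TrialRating(**row) for row in df.to_dict("records")]


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """One row per ground-truth beat (subject, trial, label, time, RR)."""
    rows = []
    for t in truth.trials:
        rr = np.concatenate([[np.nan], t.rr])
        for bt, r in zip(t.beat_times, rr):
            rows.append({"subject_id": t.subject_id, "trial_id": t.trial_id,
                         "label": t.label, "beat_time_s": bt, "rr_ms": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    truth = GroundTruth()
    for (sid, tid), grp in df.groupby(["subject_id", "trial_id"], sort=False):
        truth.trials.append(TrialTruth(
            subject_id=sid, trial_id=tid, label=int(grp["label"].iloc[0]),
            beat_times=grp["beat_time_s"].to_numpy(),
            rr=grp["rr_ms"].to_numpy()[1:],
        ))
    return truth


def write_rr(series: list[RRSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for i, (t, rr) in enumerate(zip(s.rr_times, s.rr)):
            rows.append({"subject_id": s.subject_id, "trial_id": s.trial_id,
                         "beat_index": i, "peak_time_s": t, "rr_ms": rr})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rr(path: str | Path) -> list[RRSeries]:
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    out = []
    for (sid, tid), grp in df.groupby(["subject_id", "trial_id"], sort=False):
        t = grp["peak_time_s"].to_numpy()
        rr = grp["rr_ms"].to_numpy()
        first = t[0] - rr[0] / 1000.0
        out.append(RRSeries(
            peak_times=np.concatenate([[first], t]), rr=rr, rr_times=t,
            trial_id=tid, subject_id=sid,
        ))
    return out


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject_id", "trial_id", *FEATURE_NAMES]
    features[cols].to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
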