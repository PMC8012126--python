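"""End-to-end convenience wrappers chaining the pipeline stages."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import hrv_features, preprocess, rpeak
from .exceptions import TrialInvalidError
from .hrv_features import FEATURE_NAMES
from .preprocess import EcgRecording
from .rpeak import RRSeries
from .synthetic_data import GroundTruth

logger = logging.getLogger(__name__)


def recordings_to_rr(
    recordings: list[EcgRecording],
    fs_out: float = preprocess.DEFAULT_FS_OUT,
    duration: float = preprocess.DEFAULT_TRIAL_DURATION,
) -> list[RRSeries]:
    """Downsample, denoise, segment and R-peak-detect a set of recordings.

    Trials with no usable RR series are dropped with a log entry.
    """
    out: list[RRSeries] = []
    for rec in recordings:
        ds = preprocess.downsample(rec, fs_out)
        ds.samples = preprocess.denoise_dwt(ds.samples, ds.fs)
        for seg in preprocess.segment_trials(ds, duration):
            peaks = rpeak.pan_tompkins(seg)
            try:
                out.append(rpeak.to_rr(peaks, seg.fs, seg.trial_id, seg.subject_id))
            except TrialInvalidError as exc:
                logger.warning("subject %s: %s; trial dropped", seg.subject_id, exc)
    return out


def rr_to_features(series: list[RRSeries]) -> pd.DataFrame:
    """Extract the 25-feature vector per trial; invalid trials are dropped."""
    rows = []
    for s in series:
        try:
            vec = hrv_features.extract_all(s)
        except TrialInvalidError as exc:
            logger.warning("trial %s/%s: %s; dropped", s.subject_id, s.trial_id, exc)
            continue
        rows.append({"subject_id": s.subject_id, "trial_id": s.trial_id,
                     **dict(zip(FEATURE_NAMES, vec))})
    return pd.DataFrame(rows)


def truth_to_features(truth: GroundTruth) -> pd.DataFrame:
    """Features computed from the ground-truth RR series (no waveform path).

    Useful for experiments that study the statistical stages in isolation
    from the detector, e.g. permutation-null calibrations.
    """
    series = [
        RRSeries(peak_times=t.beat_times, rr=t.rr, rr_times=t.beat_times[1:],
                 trial_id=t.trial_id, subject_id=t.subject_id)
        for t in truth.trials if len(t.rr) >= 1
    ]
    return rr_to_features(series)


def truth_labels_all(truth: GroundTruth) -> dict[tuple[str, str], str]:
    """Ground-truth class labels in the screened-label format (no exclusions)."""
    from .dataset_builder import ILFS, NON_ILFS

    return {(t.subject_id, t.trial_id): (ILFS if t.label else NON_ILFS)
            for t in truth.trials}
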