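"""Rating-based labeling, MAD outlier screening and dataset assembly.

Trials are labeled from the self reports: a trial belongs to the target
(ILFS) class when the reported impulse intensity is 2 or 3 *and* all four
Likert dimensions are high; to the non-target class when the intensity is 0
and all four dimensions are low; everything else — including intensity 1 —
is excluded.  Before model fitting, outlier trials are removed per feature
within each class with a 5 x MAD band around the median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .hrv_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: default Likert cut-offs on the 1-7 scale (symmetric around the midpoint 4)
HIGH_THRESHOLD = 5
LOW_THRESHOLD = 3
#: impulse-intensity levels admitted to the target class
ILFS_LEVELS = (2, 3)
#: MAD multiplier of the outlier band
MAD_K = 5.0

ILFS, NON_ILFS, EXCLUDED = "ilfs", "non_ilfs", "excluded"
_LIKERT_DIMS = ("arousal", "valence", "dominance", "attraction")


@dataclass(frozen=True)
class TrialRating:
    """Self report for one trial: impulse intensity 0-3 and four 1-7 scales."""

    subject_id: str
    trial_id: str
    ilfs_intensity: int
    arousal: int
    valence: int
    dominance: int
    attraction: int

    def __post_init__(self) -> None:
        if not 0 <= self.ilfs_intensity <= 3:
            raise InvalidParameterError(
                f"ilfs_intensity must be 0-3, got {self.ilfs_intensity}")
        for dim in _LIKERT_DIMS:
            v = getattr(self, dim)
            if not 1 <= v <= 7:
                raise InvalidParameterError(f"{dim} must be 1-7, got {v}")


@dataclass
class LabeledDataset:
    """Feature matrix (25 columns in canonical order), labels and provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df.insert(0, "subject_id", [p[0] for p in self.provenance])
        df.insert(1, "trial_id", [p[1] for p in self.provenance])
        df["label"] = self.y
        return df


def mad_filter(x: np.ndarray, k: float = MAD_K) -> np.ndarray:
    """Keep-mask of the MAD outlier rule.

    MAD = median_i |x_i - median_j x_j|; x_i is an outlier iff
    x_i <= median - k MAD or x_i >= median + k MAD (closed bounds: boundary
    points are removed).  A zero MAD (at least half the values identical)
    disables the rule for this feature — nothing is removed.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InvalidParameterError(f"need >= 3 values for the MAD rule, got {len(x)}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.warning("MAD = 0: outlier rule degenerate, keeping all %d values", len(x))
        return np.ones(len(x), dtype=bool)
    return (x > med - k * mad) & (x < med + k * mad)


def screen_and_label(
    ratings: list[TrialRating],
    high: int = HIGH_THRESHOLD,
    low: int = LOW_THRESHOLD,
    ilfs_levels: tuple[int, ...] = ILFS_LEVELS,
) -> dict[tuple[str, str], str]:
    """Map each trial to one of {ilfs, non_ilfs, excluded}.

    Target class: intensity in ``ilfs_levels`` and every Likert dimension
    >= ``high``.  Non-target: intensity 0 and every dimension <= ``low``.
    All other trials (notably intensity 1) are excluded.
    """
    out: dict[tuple[str, str], str] = {}
    for r in ratings:
        dims = [getattr(r, d) for d in _LIKERT_DIMS]
        if r.ilfs_intensity in ilfs_levels and all(v >= high for v in dims):
            label = ILFS
        elif r.ilfs_intensity == 0 and all(v <= low for v in dims):
            label = NON_ILFS
        else:
            label = EXCLUDED
        out[(r.subject_id, r.trial_id)] = label
    return out


def build_dataset(
    features: pd.DataFrame,
    labels: dict[tuple[str, str], str],
    mad_k: float = MAD_K,
) -> LabeledDataset:
    """Join features with screened labels and remove outlier trials.

    ``features`` must carry ``subject_id``/``trial_id`` columns plus the 25
    feature columns.  Rows with NaN sentinels are dropped with a log entry;
    the MAD rule is then applied per feature within each class and a trial is
    dropped if *any* of its features is flagged.  A class emptied by the
    screening is a fatal error.
    """
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise InvalidParameterError(f"feature columns missing: {missing}")
    df = features.copy()
    df["_label"] = [
        labels.get((s, t), EXCLUDED)
        for s, t in zip(df["subject_id"], df["trial_id"])
    ]
    df = df[df["_label"].isin([ILFS, NON_ILFS])]
    n_nan = int(df[list(FEATURE_NAMES)].isna().any(axis=1).sum())
    if n_nan:
        logger.warning("dropping %d trial(s) with missing feature values", n_nan)
        df = df.dropna(subset=list(FEATURE_NAMES))

    keep_parts = []
    for label, grp in df.groupby("_label"):
        keep = np.ones(len(grp), dtype=bool)
        if len(grp) >= 3:
            for name in FEATURE_NAMES:
                keep &= mad_filter(grp[name].to_numpy(), k=mad_k)
        dropped = int(np.sum(~keep))
        if dropped:
            logger.info("MAD screening dropped %d %s trial(s)", dropped, label)
        keep_parts.append(grp[keep])
    df = pd.concat(keep_parts) if keep_parts else df.iloc[:0]

    counts = df["_label"].value_counts()
    if counts.get(ILFS, 0) == 0 or counts.get(NON_ILFS, 0) == 0:
        raise InvalidParameterError(
            f"a class was emptied by screening (counts: {counts.to_dict()})"
        )
    df = df.sort_index()
    return LabeledDataset(
        X=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        y=(df["_label"] == ILFS).to_numpy(dtype=int),
        provenance=list(zip(df["subject_id"], df["trial_id"])),
    )
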