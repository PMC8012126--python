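"""Synthetic trial-structured ECG and self-report generator.

The study design this emulates presents a 10-s visual stimulus per trial and
records single-lead ECG at 1000 Hz; after each trial the participant reports
the intensity of the elicited affective state (0-3) and four Likert dimensions
(arousal, valence, dominance, attraction; 1-7).  No public recording of such
data exists, so this module draws trials from a simple generative model:

* the RR tachogram is a mean level plus sinusoidal low-frequency (0.1 Hz) and
  high-frequency (0.25 Hz) modulation plus white Gaussian jitter, clipped to a
  physiological range;
* the affective class shortens the mean RR interval by ``delta_rr`` (a higher
  heart rate in the target state);
* the ECG waveform is a P-QRS-T template of Gaussian bumps placed at each beat
  time, plus additive white measurement noise;
* ratings are drawn conditionally on the class (high intensity and high Likert
  scores for target trials, low for the rest) with Gaussian noise clipped to
  the scale ranges.

Everything is reproducible from the integer seed in :class:`SimulationConfig`,
and the generator returns the ground-truth beat times, RR series and class
labels so downstream stages can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_builder import TrialRating
from .exceptions import InvalidParameterError
from .preprocess import EcgRecording

#: hard physiological clip for generated RR intervals, ms
RR_FLOOR_MS = 300.0
RR_CEIL_MS = 2000.0

#: LF / HF modulation frequencies, Hz (band centres of the spectral features)
LF_FREQ = 0.1
HF_FREQ = 0.25

# P-QRS-T template: (offset from R, s), (amplitude, mV), (Gaussian width, s)
_TEMPLATE = (
    (-0.20, 0.12, 0.025),   # P
    (-0.028, -0.12, 0.010),  # Q
    (0.0, 1.0, 0.012),       # R
    (0.028, -0.18, 0.010),   # S
    (0.26, 0.25, 0.045),     # T
)
#: silent padding added around the beats of a rendered strip, s
_LEAD_IN = 0.2
_TAIL = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    ``mean_rr_non`` is the mean RR interval of non-target trials (ms); target
    trials use ``mean_rr_non - delta_rr``, i.e. a higher heart rate.
    """

    n_subjects: int = 10
    trials_per_subject: int = 20
    fs: float = 1000.0
    trial_duration: float = 10.0
    mean_rr_non: float = 800.0
    delta_rr: float = 80.0
    sdrr: float = 40.0
    lf_amp: float = 20.0
    hf_amp: float = 15.0
    noise_sd: float = 0.05
    rating_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trial_duration", "sdrr", "lf_amp", "hf_amp",
                     "noise_sd", "rating_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise InvalidParameterError("need at least one subject and one trial")
        if self.fs < 100:
            raise InvalidParameterError(f"fs={self.fs} Hz cannot represent a QRS complex")
        if self.mean_rr_non - self.delta_rr <= RR_FLOOR_MS:
            raise InvalidParameterError(
                f"mean_rr_non - delta_rr must exceed {RR_FLOOR_MS} ms"
            )


@dataclass
class TrialTruth:
    """Ground truth for one trial: class label, beat times and RR series."""

    subject_id: str
    trial_id: str
    label: int  # 1 = target state, 0 = non-target
    beat_times: np.ndarray  # s, absolute within the subject recording
    rr: np.ndarray  # ms


@dataclass
class GroundTruth:
    trials: list[TrialTruth] = field(default_factory=list)

    def labels(self) -> dict[tuple[str, str], int]:
        return {(t.subject_id, t.trial_id): t.label for t in self.trials}


def generate_rr_series(
    n_beats: int,
    mean_rr: float,
    sdrr: float,
    lf_amp: float = 0.0,
    hf_amp: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n_beats`` RR intervals (ms) from the sinusoid-plus-noise model.

    RR_i = mean_rr + lf_amp sin(2 pi 0.1 t_i) + hf_amp sin(2 pi 0.25 t_i) + eps_i,
    where t_i is the cumulative beat time (s) and eps_i ~ N(0, sdrr^2); values
    are clipped to the physiological range [300, 2000] ms.
    """
    if mean_rr <= 0:
        raise InvalidParameterError(f"mean_rr must be positive, got {mean_rr}")
    if n_beats < 2:
        raise InvalidParameterError("n_beats must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr = np.empty(n_beats)
    t = 0.0
    for i in range(n_beats):
        val = (
            mean_rr
            + lf_amp * np.sin(2 * np.pi * LF_FREQ * t)
            + hf_amp * np.sin(2 * np.pi * HF_FREQ * t)
            + (rng.normal(0.0, sdrr) if sdrr > 0 else 0.0)
        )
        rr[i] = min(max(val, RR_FLOOR_MS), RR_CEIL_MS)
        t += rr[i] / 1000.0
    return rr


def ecg_template(t: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian-bump P-QRS-T template at times ``t`` (s from R)."""
    out = np.zeros_like(t, dtype=float)
    for offset, amp, width in _TEMPLATE:
        out += amp * np.exp(-0.5 * ((t - offset) / width) ** 2)
    return out


def render_ecg(
    rr: np.ndarray,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "s0",
) -> tuple[EcgRecording, np.ndarray]:
    """Render an ECG strip from an RR series; returns (recording, beat times).

    One template is placed at each cumulative beat time (the first beat sits
    ``0.2`` s into the strip); the strip length is sum(rr)/1000 plus a fixed
    0.6 s of padding.  White noise of SD ``noise_sd`` mV is added throughout.
    """
    if fs < 100:
        raise InvalidParameterError(f"fs={fs} Hz cannot represent a QRS complex")
    rr = np.asarray(rr, dtype=float)
    beat_times = _LEAD_IN + np.concatenate(([0.0], np.cumsum(rr) / 1000.0))
    # total padding _TAIL covers the 0.2 s lead-in plus 0.4 s after the last beat
    duration = float(np.sum(rr)) / 1000.0 + _TAIL
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    half = 0.45  # template support around each R, s
    for bt in beat_times:
        lo = max(0, int((bt - half) * fs))
        hi = min(n, int((bt + half) * fs) + 1)
        samples[lo:hi] += ecg_template(t[lo:hi] - bt)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    rec = EcgRecording(samples, fs, events=[], subject_id=subject_id)
    return rec, beat_times


def generate_study(
    config: SimulationConfig,
) -> tuple[list[EcgRecording], list[TrialRating], GroundTruth]:
    """Simulate the full study: one recording per subject with trial events,
    one rating per trial, and the ground truth.

    Within each subject, half of the trials (rounded down) are target-state
    trials with mean RR reduced by ``delta_rr`` and high ratings (intensity 2
    or 3, Likert dimensions centred at 6); the rest are non-target with
    intensity 0 and dimensions centred at 2.  Trial order is shuffled.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[EcgRecording] = []
    ratings: list[TrialRating] = []
    truth = GroundTruth()
    gap = 2.0  # inter-trial baseline, s
    n_trial_samples = int(round(config.trial_duration * config.fs))
    n_gap = int(round(gap * config.fs))

    for s in range(config.n_subjects):
        subject_id = f"s{s:02d}"
        n_ilfs = config.trials_per_subject // 2
        labels = np.array([1] * n_ilfs + [0] * (config.trials_per_subject - n_ilfs))
        rng.shuffle(labels)
        chunks: list[np.ndarray] = []
        events: list[tuple[str, float]] = []
        offset = 0.0
        for j, label in enumerate(labels):
            trial_id = f"t{j:02d}"
            mean_rr = config.mean_rr_non - (config.delta_rr if label else 0.0)
            # enough beats to cover the window with margin
            lo_rr = max(mean_rr - 3 * config.sdrr - config.lf_amp - config.hf_amp,
                        RR_FLOOR_MS)
            n_beats = int(np.ceil(config.trial_duration * 1000.0 / lo_rr)) + 2
            rr = generate_rr_series(
                n_beats, mean_rr, config.sdrr, config.lf_amp, config.hf_amp, seed=rng
            )
            strip, beat_times = render_ecg(
                rr, config.fs, config.noise_sd, seed=rng, subject_id=subject_id
            )
            samples = strip.samples[:n_trial_samples]
            if len(samples) < n_trial_samples:  # pragma: no cover - margin guard
                samples = np.pad(samples, (0, n_trial_samples - len(samples)))
            in_window = beat_times < config.trial_duration
            bt = beat_times[in_window] + offset
            truth.trials.append(
                TrialTruth(subject_id, trial_id, int(label), bt, np.diff(bt) * 1000.0)
            )
            events.append((trial_id, offset))
            noise = (rng.normal(0.0, config.noise_sd, size=n_gap)
                     if config.noise_sd > 0 else np.zeros(n_gap))
            chunks.extend([samples, noise])
            offset += config.trial_duration + gap
            ratings.append(_draw_rating(rng, subject_id, trial_id, label, config))
        recordings.append(
            EcgRecording(np.concatenate(chunks), config.fs, events, subject_id)
        )
    return recordings, ratings, truth


def _draw_rating(
    rng: np.random.Generator,
    subject_id: str,
    trial_id: str,
    label: int,
    config: SimulationConfig,
) -> TrialRating:
    centre = 6.0 if label else 2.0
    dims = np.clip(
        np.rint(rng.normal(centre, config.rating_noise_sd, size=4)), 1, 7
    ).astype(int)
    intensity = int(rng.integers(2, 4)) if label else 0
    return TrialRating(
        subject_id=subject_id,
        trial_id=trial_id,
        ilfs_intensity=intensity,
        arousal=int(dims[0]),
        valence=int(dims[1]),
        dominance=int(dims[2]),
        attraction=int(dims[3]),
    )
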