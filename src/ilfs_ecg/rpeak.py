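"""Pan-Tompkins R-peak detection and RR-interval derivation.

The detector follows the classic stage chain: 5-15 Hz band-pass, five-point
derivative, point-wise squaring, 150 ms moving-window integration, then dual
adaptive thresholds with running signal/noise peak estimates, a 200 ms
refractory period and a search-back pass at 1.66x the running RR average.
Detected peaks are refined to the local maximum of the band-passed (and then
the raw) waveform, so reported peak times line up with the R wave itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import TrialInvalidError
from .preprocess import TrialSegment

logger = logging.getLogger(__name__)

#: moving-window integration length, s
INTEGRATION_WINDOW = 0.150
#: refractory period after an accepted QRS, s
REFRACTORY = 0.200
#: search-back trigger as a multiple of the running average RR
SEARCHBACK_FACTOR = 1.66
#: physiological RR validity band, ms (open interval)
RR_MIN_MS, RR_MAX_MS = 200.0, 3000.0


@dataclass
class RRSeries:
    """R-peak times (s) and the successive RR intervals (ms) of one trial.

    After validity screening every interval lies in (200, 3000) ms;
    ``rr_times`` gives the time of the beat that closes each kept interval,
    which is what the spectral features use as the tachogram abscissa.
    """

    peak_times: np.ndarray
    rr: np.ndarray
    rr_times: np.ndarray
    trial_id: str = "t0"
    subject_id: str = "s0"


def _bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def pan_tompkins(segment: TrialSegment | np.ndarray, fs: float | None = None) -> np.ndarray:
    """Detect R-peak sample indices in one ECG segment.

    Accepts a :class:`TrialSegment` or a raw sample array plus ``fs``.
    Returns a sorted integer index array; an empty array (with a warning) if
    no QRS is found, e.g. on flat input.
    """
    if isinstance(segment, TrialSegment):
        x, fs = segment.samples, segment.fs
    else:
        x = np.asarray(segment, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw sample array")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    bp = _bandpass(x, fs)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    sq = deriv**2
    win = max(1, int(round(INTEGRATION_WINDOW * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY * fs))
    cand, _ = signal.find_peaks(mwi, distance=max(1, int(round(0.06 * fs))))
    if len(cand) == 0:
        logger.warning("no candidate peaks in segment; returning empty result")
        return np.array([], dtype=int)

    # threshold initialisation from the first two seconds of integrated signal
    init = mwi[: int(2 * fs)] if len(mwi) > int(2 * fs) else mwi
    spki = float(np.max(init)) / 2.0
    npki = float(np.mean(init)) / 2.0

    qrs: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        thr1 = threshold1()
        since_last = idx - qrs[-1] if qrs else None
        if mwi[idx] > thr1 and (since_last is None or since_last > refractory):
            qrs.append(int(idx))
            spki = 0.125 * mwi[idx] + 0.875 * spki
            if len(qrs) >= 2:
                rr_history.append(qrs[-1] - qrs[-2])
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            # search-back: have we overrun 1.66x the average RR without a QRS?
            if qrs and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                if since_last is not None and since_last > SEARCHBACK_FACTOR * rr_avg:
                    window = [c for c in cand
                              if qrs[-1] + refractory < c < idx and mwi[c] > 0.5 * thr1]
                    if window:
                        back = int(max(window, key=lambda c: mwi[c]))
                        qrs.append(back)
                        spki = 0.25 * mwi[back] + 0.75 * spki
                        rr_history.append(qrs[-1] - qrs[-2])
                        qrs.sort()

    if not qrs:
        logger.warning("no QRS accepted in segment; returning empty result")
        return np.array([], dtype=int)

    # refine to the R wave: band-passed local maximum, then raw local maximum
    refined: list[int] = []
    w_bp = int(round(0.10 * fs))
    w_raw = int(round(0.03 * fs))
    for idx in qrs:
        lo, hi = max(0, idx - w_bp), min(len(x), idx + w_bp + 1)
        p = lo + int(np.argmax(bp[lo:hi]))
        lo, hi = max(0, p - w_raw), min(len(x), p + w_raw + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = sorted(set(refined))

    # enforce the refractory spacing after refinement (keep the taller peak)
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


def to_rr(
    peaks: np.ndarray,
    fs: float,
    trial_id: str = "t0",
    subject_id: str = "s0",
) -> RRSeries:
    """Convert peak indices to an RR series, screening implausible intervals.

    Intervals of 200 ms or less are treated as false detections: the second
    peak of the pair is discarded.  Intervals of 3000 ms or more (missed
    beats) are dropped from the series.  Fewer than two surviving peaks make
    the trial invalid.
    """
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        raise TrialInvalidError(f"trial {trial_id}: need >= 2 peaks, got {len(peaks)}")
    kept = [int(peaks[0])]
    for p in peaks[1:]:
        if 1000.0 * (p - kept[-1]) / fs <= RR_MIN_MS:
            logger.warning("trial %s: interval <= %g ms screened out", trial_id, RR_MIN_MS)
        else:
            kept.append(int(p))
    if len(kept) < 2:
        raise TrialInvalidError(f"trial {trial_id}: no valid RR interval after screening")
    times = np.array(kept) / fs
    rr = np.diff(times) * 1000.0
    ok = rr < RR_MAX_MS
    if not np.all(ok):
        logger.warning("trial %s: %d interval(s) >= %g ms dropped",
                       trial_id, int(np.sum(~ok)), RR_MAX_MS)
    if not np.any(ok):
        raise TrialInvalidError(f"trial {trial_id}: no valid RR interval after screening")
    return RRSeries(
        peak_times=times,
        rr=rr[ok],
        rr_times=times[1:][ok],
        trial_id=trial_id,
        subject_id=subject_id,
    )
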