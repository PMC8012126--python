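"""The 25 heart-rate-variability features computed per 10-s trial.

Feature indices #1-#25 and their canonical order:

==  ============  =====================================================
#   symbol        description
==  ============  =====================================================
1   Mean_RR       mean of RR intervals (ms)
2   CVRR          coefficient of variation of RR intervals
3   SDRR          sample SD of RR intervals (ms)
4   RMSSD         root mean square of successive differences (ms)
5   MSD           mean absolute successive difference (ms)
6   SDSD          sample SD of successive differences (ms)
7   NN50          count of |successive difference| > 50 ms
8   PNN50         NN50 as a percentage of the differences
9   NN20          count of |successive difference| > 20 ms
10  PNN20         NN20 as a percentage of the differences
11  Mean_HR       mean instantaneous heart rate, mean(60000 / RR_i) (bpm)
12  QD            quartile deviation (Q3 - Q1) / 2 of RR (ms)
13  SD1           Poincare SD along the -45 deg (T) axis (ms)
14  SD2           Poincare SD along the +45 deg (L) axis (ms)
15  SD1_SD2       SD1 / SD2
16  CSI           cardiac sympathetic index, L / T with L = 4 SD2, T = 4 SD1
17  CVI           cardiac vagal index, log10(L * T)
18  Modified_CSI  L^2 / T (ms)
19  LZC           normalized Lempel-Ziv (LZ76) complexity of the
                  median-binarized RR sequence
20  TP            spectral power, 0.04-0.4 Hz (Lomb-Scargle)
21  LF            spectral power, 0.04-0.15 Hz
22  HF            spectral power, 0.15-0.4 Hz
23  LF_HF         LF / HF
24  nLFP          LF / (LF + HF)
25  nHFP          HF / (LF + HF)
==  ============  =====================================================

Ratio features on a degenerate (constant) RR series are returned as NaN and
the trial is later excluded from model input.  The spectral features use the
Lomb-Scargle periodogram of the unevenly sampled (beat time, RR) tachogram
directly, with no resampling: a 10-s window has too few beats for a
Welch-type estimate, and the 0.04 Hz band edge is retained even though such a
short window cannot truly resolve it (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lombscargle

from .exceptions import TrialInvalidError
from .rpeak import RRSeries

FEATURE_NAMES: tuple[str, ...] = (
    "Mean_RR", "CVRR", "SDRR", "RMSSD", "MSD", "SDSD",
    "NN50", "PNN50", "NN20", "PNN20", "Mean_HR", "QD",
    "SD1", "SD2", "SD1_SD2", "CSI", "CVI", "Modified_CSI", "LZC",
    "TP", "LF", "HF", "LF_HF", "nLFP", "nHFP",
)

#: spectral band edges, Hz
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def time_domain(rr: np.ndarray) -> dict[str, float]:
    """Features #1-#12 from an RR series (ms). Sample (n-1) SDs throughout."""
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 4:
        raise TrialInvalidError(f"need >= 4 RR intervals, got {len(rr)}")
    d = np.diff(rr)
    mean_rr = float(np.mean(rr))
    sdrr = float(np.std(rr, ddof=1))
    q1, q3 = np.percentile(rr, [25, 75])
    nn50 = int(np.sum(np.abs(d) > 50.0))
    nn20 = int(np.sum(np.abs(d) > 20.0))
    return {
        "Mean_RR": mean_rr,
        "CVRR": sdrr / mean_rr,
        "SDRR": sdrr,
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "MSD": float(np.mean(np.abs(d))),
        "SDSD": float(np.std(d, ddof=1)),
        "NN50": nn50,
        "PNN50": 100.0 * nn50 / len(d),
        "NN20": nn20,
        "PNN20": 100.0 * nn20 / len(d),
        "Mean_HR": float(np.mean(60000.0 / rr)),
        "QD": float((q3 - q1) / 2.0),
    }


def poincare(rr: np.ndarray) -> dict[str, float]:
    """Features #13-#18 from the (RR_i, RR_{i+1}) Poincare scatter.

    SD1 is the dispersion across the identity line, sqrt(var(diff)/2) with
    the population (n) variance — the convention of the Poincare literature —
    and SD2 along it, defined through the rotation identity
    SD1^2 + SD2^2 = 2 SDRR^2 (SDRR keeps the sample convention of feature
    #3).  SD1 equals the population SDSD / sqrt(2) exactly.  The ellipse
    axes T = 4 SD1 and
    L = 4 SD2 give CSI = L/T, CVI = log10(L*T) and modified CSI = L^2/T; all
    three are NaN for a degenerate (constant) series.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 4:
        raise TrialInvalidError(f"need >= 4 RR intervals, got {len(rr)}")
    d = np.diff(rr)
    sdrr = np.std(rr, ddof=1)
    sd1 = float(np.sqrt(np.var(d, ddof=0) / 2.0))
    sd2 = float(np.sqrt(max(2.0 * sdrr**2 - sd1**2, 0.0)))
    t_axis, l_axis = 4.0 * sd1, 4.0 * sd2
    degenerate = sd1 == 0.0 or sd2 == 0.0
    return {
        "SD1": sd1,
        "SD2": sd2,
        "SD1_SD2": sd1 / sd2 if sd2 > 0 else float("nan"),
        "CSI": l_axis / t_axis if not degenerate else float("nan"),
        "CVI": float(np.log10(l_axis * t_axis)) if not degenerate else float("nan"),
        "Modified_CSI": l_axis**2 / t_axis if not degenerate else float("nan"),
    }


def lz76_phrase_count(symbols) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing.

    A phrase is grown while it can be reproduced from the text preceding its
    last symbol, and cut (as a new phrase) at the first symbol that makes it
    novel.  A constant sequence therefore parses into exactly two phrases.
    """
    s = "".join(str(int(b)) for b in symbols)
    n = len(s)
    c, i = 0, 0
    while i < n:
        k = 1
        while i + k <= n and s[i : i + k] in s[: i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def lz_complexity(rr: np.ndarray) -> float:
    """Feature #19: normalized LZ76 complexity, c(n) log2(n) / n.

    The RR series is binarized at its median (>= median -> 1), so the value
    depends only on the rank pattern of the series.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 8:
        raise TrialInvalidError(f"need >= 8 RR intervals for LZC, got {len(rr)}")
    bits = (rr >= np.median(rr)).astype(int)
    n = len(bits)
    return lz76_phrase_count(bits) * np.log2(n) / n


def frequency_domain(
    rrs: RRSeries, n_freq: int = 721
) -> dict[str, float]:
    """Features #20-#25 from the Lomb-Scargle periodogram of the tachogram.

    The mean-removed RR values at their beat times feed the periodogram on a
    shared 0.04-0.4 Hz grid containing the 0.15 Hz band edge, so trapezoidal
    LF and HF powers add up to TP exactly.  Powers are on a variance scale
    (ms^2): a pure RR modulation of amplitude A integrates to about A^2/2.
    """
    t = np.asarray(rrs.rr_times, dtype=float)
    x = np.asarray(rrs.rr, dtype=float)
    if len(x) < 4 or (rrs.peak_times[-1] - rrs.peak_times[0]) < 5.0:
        raise TrialInvalidError("need >= 4 beats spanning >= 5 s for spectral features")
    x = x - np.mean(x)
    freqs = np.linspace(LF_BAND[0], HF_BAND[1], n_freq)  # grid contains 0.15 Hz
    power = lombscargle(t, x, 2 * np.pi * freqs) * 2.0 / len(x)
    lf_mask = freqs <= LF_BAND[1]
    hf_mask = freqs >= HF_BAND[0]
    tp = float(np.trapezoid(power, freqs))
    lf = float(np.trapezoid(power[lf_mask], freqs[lf_mask]))
    hf = float(np.trapezoid(power[hf_mask], freqs[hf_mask]))
    return {
        "TP": tp,
        "LF": lf,
        "HF": hf,
        "LF_HF": lf / hf if hf > 0 else float("nan"),
        "nLFP": lf / (lf + hf) if lf + hf > 0 else float("nan"),
        "nHFP": hf / (lf + hf) if lf + hf > 0 else float("nan"),
    }


def extract_all(rrs: RRSeries) -> np.ndarray:
    """Full 25-feature vector (order of :data:`FEATURE_NAMES`) for one trial.

    NaN sentinels from degenerate sub-computations propagate; a trial too
    short for any feature group raises :class:`TrialInvalidError`.
    """
    values: dict[str, float] = {}
    values.update(time_domain(rrs.rr))
    values.update(poincare(rrs.rr))
    values["LZC"] = lz_complexity(rrs.rr)
    values.update(frequency_domain(rrs))
    return np.array([values[name] for name in FEATURE_NAMES], dtype=float)
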