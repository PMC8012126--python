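"""Independent brute-force oracles used by the tests.

Everything here is written directly from first-principles definitions using
plain Python / numpy primitives, deliberately NOT reusing any code path from
the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def time_domain_oracle(rr: np.ndarray) -> dict[str, float]:
    """Direct formula evaluation of the 12 time-domain descriptors."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean_rr = sum(rr) / n
    var = sum((v - mean_rr) ** 2 for v in rr) / (n - 1)
    sdrr = math.sqrt(var)
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    md = sum(d) / len(d)
    sdsd = math.sqrt(sum((v - md) ** 2 for v in d) / (len(d) - 1))
    rmssd = math.sqrt(sum(v * v for v in d) / len(d))
    msd = sum(abs(v) for v in d) / len(d)
    nn50 = sum(1 for v in d if abs(v) > 50)
    nn20 = sum(1 for v in d if abs(v) > 20)
    q1, q3 = np.percentile(rr, [25, 75])
    return {
        "Mean_RR": mean_rr,
        "CVRR": sdrr / mean_rr,
        "SDRR": sdrr,
        "RMSSD": rmssd,
        "MSD": msd,
        "SDSD": sdsd,
        "NN50": nn50,
        "PNN50": 100.0 * nn50 / (n - 1),
        "NN20": nn20,
        "PNN20": 100.0 * nn20 / (n - 1),
        "Mean_HR": sum(60000.0 / v for v in rr) / n,
        "QD": (q3 - q1) / 2.0,
    }


def poincare_oracle(rr: np.ndarray) -> dict[str, float]:
    """Poincare descriptors evaluated directly from their definitions:
    sd1 = sqrt(var_pop(diff)/2), sd2 = sqrt(2 var_sample(rr) - sd1^2), and
    the ellipse-axis indices from T = 4 sd1, L = 4 sd2."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean_rr = sum(rr) / n
    var_rr = sum((v - mean_rr) ** 2 for v in rr) / (n - 1)
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    md = sum(d) / len(d)
    var_d = sum((v - md) ** 2 for v in d) / len(d)  # population convention
    sd1 = math.sqrt(var_d / 2.0)
    sd2 = math.sqrt(max(2.0 * var_rr - sd1 * sd1, 0.0))
    t_ax, l_ax = 4.0 * sd1, 4.0 * sd2
    if sd1 == 0 or sd2 == 0:
        nan = float("nan")
        return {"SD1": sd1, "SD2": sd2, "SD1_SD2": nan, "CSI": nan,
                "CVI": nan, "Modified_CSI": nan}
    return {
        "SD1": sd1,
        "SD2": sd2,
        "SD1_SD2": sd1 / sd2,
        "CSI": l_ax / t_ax,
        "CVI": math.log10(l_ax * t_ax),
        "Modified_CSI": l_ax * l_ax / t_ax,
    }


def auc_oracle(y_true, scores) -> float:
    """AUC as the normalized count of concordant pairs (ties count half)."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def mannwhitney_exact_p(a, b) -> float:
    """Exact two-sided rank-sum p-value by full enumeration (no ties)."""
    a, b = list(a), list(b)
    combined = a + b
    n1 = len(a)
    ranks = {v: r + 1 for r, v in enumerate(sorted(combined))}
    u_of = lambda grp: sum(ranks[v] for v in grp) - n1 * (n1 + 1) / 2
    u_obs = u_of(a)
    mu = len(a) * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(combined)), n1):
        grp = [combined[i] for i in idx]
        u = sum(ranks[v] for v in grp) - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def beat_match_stats(detected_s, truth_s, tol_s=0.020) -> tuple[int, int, int]:
    """Greedy one-to-one matching of beat times; returns (tp, fp, fn)."""
    detected = sorted(detected_s)
    truth = sorted(truth_s)
    used = [False] * len(truth)
    tp = 0
    for d in detected:
        best, best_err = None, tol_s
        for i, t in enumerate(truth):
            if not used[i] and abs(d - t) <= best_err:
                best, best_err = i, abs(d - t)
        if best is not None:
            used[best] = True
            tp += 1
    return tp, len(detected) - tp, len(truth) - tp


def detection_f1(detected_s, truth_s, tol_s=0.020) -> float:
    tp, fp, fn = beat_match_stats(detected_s, truth_s, tol_s)
    return 2 * tp / (2 * tp + fp + fn) if tp else 0.0
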