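"""Independent brute-force reference implementations used as test oracles.

Everything here is written directly from the defining formulas, with
plain Python loops and no reuse of package internals, so agreement with
the package is a genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np


def apen_bruteforce(x, m, r):
    """Approximate entropy by direct double loops (self-matches included)."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = 0
            for tj in templates:
                if max(abs(a - b) for a, b in zip(ti, tj)) <= r:
                    c += 1
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    """Sample entropy by direct pair counting (self-matches excluded).

    Both template lengths use the first n-m starting positions.
    """
    x = list(map(float, x))
    n = len(x)
    tm = [x[i : i + m] for i in range(n - m)]
    tm1 = [x[i : i + m + 1] for i in range(n - m)]

    def count(templates):
        c = 0
        for i in range(len(templates)):
            for j in range(len(templates)):
                if i == j:
                    continue
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    B = count(tm)
    A = count(tm1)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def ctm_bruteforce(x, rho):
    """Central tendency measure by direct enumeration."""
    x = list(map(float, x))
    n = len(x)
    inside = 0
    total = 0
    for i in range(n - 2):
        d1 = x[i + 1] - x[i]
        d2 = x[i + 2] - x[i + 1]
        total += 1
        if math.sqrt(d1 * d1 + d2 * d2) < rho:
            inside += 1
    return inside / total


def berger_counts_bruteforce(peak_times, window_starts, window_ends):
    """Fractional interval counts in [start, end] by direct overlap sums."""
    t = list(map(float, peak_times))
    out = []
    for a, b in zip(window_starts, window_ends):
        total = 0.0
        for i in range(len(t) - 1):
            lo, hi = t[i], t[i + 1]
            overlap = min(hi, b) - max(lo, a)
            if overlap > 0:
                total += overlap / (hi - lo)
        out.append(total)
    return np.asarray(out)


def auc_bruteforce(scores, y):
    """AUC as the all-pairs concordance fraction (ties count 1/2)."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def confusion_bruteforce(scores, y, threshold):
    """Confusion-table metrics (percent) by direct enumeration."""
    tp = fn = tn = fp = 0
    for s, lab in zip(scores, y):
        pred = s >= threshold
        if lab == 1 and pred:
            tp += 1
        elif lab == 1:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    n = tp + fn + tn + fp

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "accuracy": pct(tp + tn, n),
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
        "referred_pct": pct(tp + fp, n),
    }


def delta_index_bruteforce(x, block):
    """Delta index from explicit block means."""
    means = []
    for start in range(0, len(x) - block + 1, block):
        chunk = [v for v in x[start : start + block] if not math.isnan(v)]
        if chunk:
            means.append(sum(chunk) / len(chunk))
    diffs = [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]
    return sum(diffs) / len(diffs)
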