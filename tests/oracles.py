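"""Independent brute-force oracles used to pin the metric implementations.

These deliberately avoid the vectorised code paths of the package: pair
metrics are computed by explicit enumeration, least-squares fits by direct
formulas on Python floats.
"""

from itertools import combinations

import numpy as np


def ci_oracle(y, yhat) -> float:
    """O(n^2) enumeration of comparable pairs with half credit for ties."""
    num = den = 0.0
    for i, j in combinations(range(len(y)), 2):
        if y[i] == y[j]:
            continue
        den += 1
        lo, hi = (i, j) if y[i] < y[j] else (j, i)
        if yhat[lo] < yhat[hi]:
            num += 1
        elif yhat[lo] == yhat[hi]:
            num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def auc_oracle(y, p) -> float:
    """Probability a random positive outranks a random negative, ties 1/2."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    num = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                num += 1
            elif a == b:
                num += 0.5
    return num / (len(pos) * len(neg))


def confusion_oracle(y, p, threshold=0.5):
    tp = sum(1 for yi, pi in zip(y, p) if yi == 1 and pi >= threshold)
    tn = sum(1 for yi, pi in zip(y, p) if yi == 0 and pi < threshold)
    fp = sum(1 for yi, pi in zip(y, p) if yi == 0 and pi >= threshold)
    fn = sum(1 for yi, pi in zip(y, p) if yi == 1 and pi < threshold)
    return tp, tn, fp, fn


def mcc_oracle(y, p, threshold=0.5) -> float:
    tp, tn, fp, fn = confusion_oracle(y, p, threshold)
    den = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) ** 0.5
    if den == 0:
        raise ZeroDivisionError("degenerate confusion table")
    return (tp * tn - fp * fn) / den


def accuracy_oracle(y, p, threshold=0.5) -> float:
    tp, tn, fp, fn = confusion_oracle(y, p, threshold)
    return (tp + tn) / (tp + tn + fp + fn)


def regression_oracle(y, yhat):
    y = [float(v) for v in y]
    yhat = [float(v) for v in yhat]
    n = len(y)
    mse = sum((a - b) ** 2 for a, b in zip(y, yhat)) / n
    ybar = sum(y) / n
    ss_tot = sum((a - ybar) ** 2 for a in y)
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
    r2 = 1 - ss_res / ss_tot
    phat = sum(yhat) / n
    cov = sum((a - ybar) * (b - phat) for a, b in zip(y, yhat))
    sy = sum((a - ybar) ** 2 for a in y) ** 0.5
    sp = sum((b - phat) ** 2 for b in yhat) ** 0.5
    pearson = cov / (sy * sp)
    return mse, r2, pearson


def rm2_oracle(y, yhat):
    """Two least-squares fits computed from first principles."""
    y = [float(v) for v in y]
    yhat = [float(v) for v in yhat]
    _, _, r = regression_oracle(y, yhat)
    r2 = r * r
    k = sum(a * b for a, b in zip(y, yhat)) / sum(b * b for b in yhat)
    ybar = sum(y) / len(y)
    ss_tot = sum((a - ybar) ** 2 for a in y)
    r0_2 = 1 - sum((a - k * b) ** 2 for a, b in zip(y, yhat)) / ss_tot
    rad = max(r2 - r0_2, 0.0)
    return r2 * (1 - rad**0.5), r2, r0_2
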