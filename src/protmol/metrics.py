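"""Evaluation metrics for affinity regression and interaction classification.

Regression reports MSE, the coefficient of determination R^2 (1 - SSres/SStot,
which is not the squared Pearson correlation), Pearson r, the concordance
index CI, and the QSAR validation metric

    rm^2 = r^2 * (1 - sqrt(r^2 - r0^2)),

where r^2 is the squared Pearson correlation of observed vs predicted (fit
with intercept) and r0^2 the coefficient of determination of the
through-origin fit of observed on predicted.  Classification reports
accuracy, Matthews correlation coefficient (MCC) and ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score


class MetricUndefinedError(ValueError):
    """The metric is undefined for the given inputs (e.g. zero variance)."""


def _as_1d(*arrays, min_len: int = 1):
    out = []
    n = None
    for a in arrays:
        a = np.asarray(a, dtype=float).ravel()
        if n is None:
            n = a.size
        elif a.size != n:
            raise ValueError(f"length mismatch: {a.size} vs {n}")
        out.append(a)
    if n < min_len:
        raise ValueError(f"need at least {min_len} values, got {n}")
    return out


def regression_metrics(y, yhat) -> dict[str, float]:
    """Return ``{"mse", "r_squared", "pearson_r"}`` for observed vs predicted."""
    y, yhat = _as_1d(y, yhat, min_len=2)
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        raise MetricUndefinedError("r_squared undefined: zero variance in y")
    r_squared = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if np.std(yhat) == 0.0 or np.std(y) == 0.0:
        raise MetricUndefinedError("pearson_r undefined: zero variance input")
    pearson = float(stats.pearsonr(y, yhat).statistic)
    return {"mse": mse, "r_squared": r_squared, "pearson_r": pearson}


def concordance_index(y, yhat) -> float:
    """Fraction of correctly ordered comparable pairs.

    A pair (i, j) is comparable when y_i != y_j.  A comparable pair counts 1
    when the predictions are ordered like the labels, 1/2 when the
    predictions are tied, and 0 otherwise.
    """
    y, yhat = _as_1d(y, yhat, min_len=2)
    # vectorised over the upper triangle of the pair matrix
    dy = y[:, None] - y[None, :]
    dp = yhat[:, None] - yhat[None, :]
    iu = np.triu_indices(y.size, k=1)
    dy, dp = dy[iu], dp[iu]
    comparable = dy != 0
    n_comp = int(np.count_nonzero(comparable))
    if n_comp == 0:
        raise MetricUndefinedError("concordance index undefined: no comparable pairs")
    dy, dp = dy[comparable], dp[comparable]
    concordant = np.count_nonzero(np.sign(dy) == np.sign(dp))
    tied = np.count_nonzero(dp == 0)
    return float((concordant + 0.5 * tied) / n_comp)


def rm_squared(y, yhat, radical: bool = True) -> dict[str, float]:
    """QSAR rm^2 metric with its r^2 and r0^2 components.

    ``radical=False`` selects the variant rm^2 = r^2 * (1 - (r^2 - r0^2)),
    without the square root.
    """
    y, yhat = _as_1d(y, yhat, min_len=3)
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        raise MetricUndefinedError("rm_squared undefined: zero variance input")
    r = float(stats.pearsonr(y, yhat).statistic)
    r2 = r * r
    denom = float(np.sum(yhat**2))
    if denom == 0.0:
        raise MetricUndefinedError("through-origin fit undefined: all predictions zero")
    k = float(np.sum(y * yhat)) / denom
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r0_2 = 1.0 - float(np.sum((y - k * yhat) ** 2)) / ss_tot
    radicand = r2 - r0_2
    if radicand < 0:
        if radicand < -1e-9:  # beyond float rounding of the two fits
            warnings.warn(
                f"r0^2 ({r0_2:.6g}) exceeds r^2 ({r2:.6g}); clipping radicand to 0",
                stacklevel=2,
            )
        radicand = 0.0
    penalty = float(np.sqrt(radicand)) if radical else radicand
    return {"rm_squared": float(r2 * (1.0 - penalty)), "r2": r2, "r0_2": r0_2}


def binary_metrics(y, p, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, MCC and ROC-AUC for binary labels and predicted probabilities.

    MCC and ROC-AUC require both classes in ``y``; accuracy is always
    defined.  MCC additionally requires a non-degenerate confusion table
    (at least one predicted positive and one predicted negative).
    """
    y, p = _as_1d(y, p, min_len=1)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    pred = (p >= threshold).astype(float)
    accuracy = float(np.mean(pred == y))
    if len(np.unique(y)) < 2:
        raise MetricUndefinedError(
            f"mcc/roc_auc undefined for single-class labels (accuracy={accuracy})"
        )
    if len(np.unique(pred)) < 2:
        raise MetricUndefinedError(
            f"mcc undefined: all predictions on one side of the threshold "
            f"(accuracy={accuracy})"
        )
    mcc = float(matthews_corrcoef(y, pred))
    auc = float(roc_auc_score(y, p))
    return {"accuracy": accuracy, "mcc": mcc, "roc_auc": auc}


@dataclass
class MetricReport:
    """Container for per-evaluation metric values; fields unset for the task stay None."""

    mse: float | None = None
    r_squared: float | None = None
    pearson_r: float | None = None
    concordance_index: float | None = None
    rm_squared: float | None = None
    rm_r2: float | None = None
    rm_r0_2: float | None = None
    accuracy: float | None = None
    mcc: float | None = None
    roc_auc: float | None = None

    def to_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def evaluate(y, yhat, task: str) -> MetricReport:
    """Compute the full metric panel for one evaluation set."""
    if task == "regression":
        reg = regression_metrics(y, yhat)
        rm = rm_squared(y, yhat)
        return MetricReport(
            mse=reg["mse"],
            r_squared=reg["r_squared"],
            pearson_r=reg["pearson_r"],
            concordance_index=concordance_index(y, yhat),
            rm_squared=rm["rm_squared"],
            rm_r2=rm["r2"],
            rm_r0_2=rm["r0_2"],
        )
    if task == "binary_classification":
        try:
            b = binary_metrics(y, yhat)
        except MetricUndefinedError:
            # degenerate thresholded predictions (e.g. a signal-free model on
            # imbalanced data): accuracy is still defined, mcc/roc_auc are not
            y_arr, p_arr = _as_1d(y, yhat)
            return MetricReport(accuracy=float(np.mean((p_arr >= 0.5) == y_arr)))
        return MetricReport(accuracy=b["accuracy"], mcc=b["mcc"], roc_auc=b["roc_auc"])
    raise ValueError(f"unknown task {task!r}")
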