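"""Gradient-boosting ensemble over learned representations.

Three boosted-tree models are trained on three feature views of each
interaction record — the joint cls vector, the concatenated mean-pooled
protein and molecule vectors, and all three concatenated — and combined by
a weighted mean.  Hyperparameters are tuned per model by pure random search
(2 000 iterations at full scale); the ensemble weights are fitted on
validation predictions over a simplex grid (step 0.05, 231 candidates);
finalists are retrained on train + validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator

from .metrics import MetricUndefinedError, binary_metrics

VARIANTS = ("cls_only", "pooled_pair", "all")


class SearchSpaceError(ValueError):
    pass


class LeakageError(ValueError):
    pass


@dataclass(frozen=True)
class GbmHyperparams:
    learning_rate: float
    max_tree_depth: int
    lambda_reg: float
    alpha_reg: float
    max_delta_step: float
    min_child_weight: float
    num_rounds: int
    negative_class_weight: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


# (low, high, sampling) per field; sampling in {"log", "uniform", "int"}
DEFAULT_SPACE: dict[str, tuple[float, float, str]] = {
    "learning_rate": (1e-3, 0.5, "log"),
    "max_tree_depth": (2, 14, "int"),
    "lambda_reg": (1e-4, 1e2, "log"),
    "alpha_reg": (1e-4, 1e2, "log"),
    "max_delta_step": (0.0, 10.0, "uniform"),
    "min_child_weight": (0.1, 100.0, "log"),
    "num_rounds": (20, 2000, "int"),
    "negative_class_weight": (0.1, 1.0, "uniform"),
}

# reduced ranges for desk-scale runs: shallower trees and fewer rounds keep a
# 50-trial search fast on a thousand training rows
SCALED_SPACE: dict[str, tuple[float, float, str]] = {
    **DEFAULT_SPACE,
    "max_tree_depth": (2, 8, "int"),
    "num_rounds": (20, 300, "int"),
}


def sample_hyperparams(space: Mapping, rng: np.random.Generator, task: str) -> GbmHyperparams:
    """Draw every field independently from its range."""
    out = {}
    for name, (lo, hi, kind) in space.items():
        if name == "negative_class_weight" and task != "binary_classification":
            continue
        if lo > hi or (kind == "int" and int(lo) > int(hi)):
            raise SearchSpaceError(f"degenerate range for {name}: ({lo}, {hi})")
        if kind == "log":
            v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "uniform":
            v = float(rng.uniform(lo, hi))
        elif kind == "int":
            v = int(rng.integers(int(lo), int(hi) + 1))
        else:
            raise SearchSpaceError(f"unknown sampling kind {kind!r}")
        out[name] = v
    if task != "binary_classification":
        out["negative_class_weight"] = None
    return GbmHyperparams(**out)


@dataclass
class TrainedGbm:
    booster: xgb.Booster
    hyperparams: GbmHyperparams
    task: str
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not "
                f"match trained width {self.n_features}"
            )
        return self.booster.predict(xgb.DMatrix(X))


def train_gbm(
    X: np.ndarray,
    y: Sequence[float],
    hp: GbmHyperparams,
    task: str = "regression",
    seed: int = 0,
) -> TrainedGbm:
    """Train one boosted-tree model; deterministic given the seed."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows for {y.shape[0]} labels")
    params = {
        "eta": hp.learning_rate,
        "max_depth": int(hp.max_tree_depth),
        "lambda": hp.lambda_reg,
        "alpha": hp.alpha_reg,
        "max_delta_step": hp.max_delta_step,
        "min_child_weight": hp.min_child_weight,
        "objective": "binary:logistic" if task == "binary_classification" else "reg:squarederror",
        "tree_method": "hist",
        "max_bin": 64,  # coarse histogram bins: ample for desk-scale row counts
        "nthread": 1,
        "seed": seed,
    }
    weights = None
    if task == "binary_classification" and hp.negative_class_weight is not None:
        weights = np.where(y == 0.0, hp.negative_class_weight, 1.0)
    dtrain = xgb.DMatrix(X, label=y, weight=weights)
    booster = xgb.train(params, dtrain, num_boost_round=int(hp.num_rounds))
    return TrainedGbm(booster=booster, hyperparams=hp, task=task, n_features=X.shape[1])


def _val_score(model: TrainedGbm, Xva, yva, task: str) -> float:
    """Higher is better: negative MSE for regression, MCC for classification.

    An undefined MCC (all thresholded predictions on one side) scores -2,
    below the worst defined MCC, so the search still returns a model when no
    candidate separates the classes.
    """
    pred = model.predict(Xva)
    if task == "regression":
        return -float(np.mean((pred - np.asarray(yva)) ** 2))
    try:
        return binary_metrics(yva, pred)["mcc"]
    except MetricUndefinedError:
        return -2.0


def random_search(
    Xtr: np.ndarray,
    ytr: Sequence[float],
    Xva: np.ndarray,
    yva: Sequence[float],
    space: Mapping | None = None,
    n_iter: int = 2000,
    seed: int = 0,
    task: str = "regression",
) -> tuple[GbmHyperparams, pd.DataFrame]:
    """Pure random hyperparameter search; returns the best set and a trials log."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    space = space or DEFAULT_SPACE
    if not space:
        raise SearchSpaceError("empty search space")
    rng = np.random.default_rng(seed)
    trials = []
    best: tuple[float, GbmHyperparams | None] = (-np.inf, None)
    for t in range(n_iter):
        hp = sample_hyperparams(space, rng, task)
        model = train_gbm(Xtr, ytr, hp, task=task, seed=seed)
        score = _val_score(model, Xva, yva, task)
        trials.append({"trial": t, **hp.to_dict(), "val_score": score})
        if score > best[0]:
            best = (score, hp)
    if best[1] is None:
        raise RuntimeError("no trial produced a finite validation score")
    return best[1], pd.DataFrame(trials)


def simplex_grid(step: float = 0.05) -> list[tuple[float, float, float]]:
    """All (w1, w2, w3) on the simplex with the given step, lexicographic order."""
    n = int(round(1.0 / step))
    out = []
    for i in range(n + 1):
        for j in range(n - i + 1):
            out.append((i / n, j / n, (n - i - j) / n))
    return out


def fit_ensemble_weights(
    val_preds: Sequence[np.ndarray],
    val_labels: Sequence[float],
    task: str = "regression",
    step: float = 0.05,
) -> tuple[float, float, float]:
    """Exhaustive simplex-grid search for the prediction weights.

    Regression minimises validation MSE; classification maximises MCC.
    Ties keep the earliest grid point in lexicographic (w1, w2, w3) order.
    """
    preds = [np.asarray(p, dtype=float) for p in val_preds]
    y = np.asarray(val_labels, dtype=float)
    if len(preds) != 3:
        raise ValueError("expected exactly three prediction vectors")
    for p in preds:
        if p.shape != y.shape:
            raise ValueError(f"prediction length {p.shape} != labels {y.shape}")
    P = np.stack(preds, axis=1)  # (n, 3)
    best_w, best_score = None, -np.inf
    for w in simplex_grid(step):
        mix = P @ np.asarray(w)
        if task == "regression":
            score = -float(np.mean((mix - y) ** 2))
        else:
            try:
                score = binary_metrics(y, mix)["mcc"]
            except MetricUndefinedError:
                score = -2.0
        # strict improvement beyond float noise: ties keep the earliest
        # grid point in lexicographic (w1, w2, w3) order
        if best_w is None or score - best_score > 1e-12 * max(1.0, abs(best_score)):
            best_w, best_score = w, score
    return best_w


def ensemble_predict(
    models: Mapping[str, TrainedGbm],
    weights: Sequence[float],
    features: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Weighted mean of the three per-variant model predictions."""
    missing = [v for v in VARIANTS if v not in features]
    if missing:
        raise ValueError(f"missing features for variants: {missing}")
    preds = [models[v].predict(features[v]) for v in VARIANTS]
    w = np.asarray(weights, dtype=float)
    return np.stack(preds, axis=1) @ w


class BoostedRepresentationEnsemble(BaseEstimator):
    """Three boosted-tree models over feature variants plus simplex weights.

    ``fit`` takes per-variant feature matrices for train and validation:
    hyperparameters are selected per variant by random search on the
    validation score, ensemble weights are fitted on validation predictions,
    and the final models are retrained on train + validation with the
    selected hyperparameters (weights carried over unchanged).

    Fitted attributes: ``models_`` (variant -> TrainedGbm), ``weights_``,
    ``hyperparams_``, ``trials_`` (variant -> DataFrame).
    """

    def __init__(
        self,
        task: str = "regression",
        n_iter: int = 2000,
        space: Mapping | None = None,
        weight_step: float = 0.05,
        seed: int = 0,
    ):
        self.task = task
        self.n_iter = n_iter
        self.space = space
        self.weight_step = weight_step
        self.seed = seed

    def fit(
        self,
        features_train: Mapping[str, np.ndarray],
        y_train: Sequence[float],
        features_val: Mapping[str, np.ndarray],
        y_val: Sequence[float],
        test_keys: set | None = None,
        train_keys: Sequence | None = None,
    ) -> "BoostedRepresentationEnsemble":
        if test_keys is not None and train_keys is not None:
            leaked = set(train_keys) & set(test_keys)
            if leaked:
                raise LeakageError(f"{len(leaked)} records appear in both train+val and test")
        space = self.space or DEFAULT_SPACE
        self.hyperparams_ = {}
        self.trials_ = {}
        val_preds = []
        for vi, variant in enumerate(VARIANTS):
            hp, log = random_search(
                features_train[variant],
                y_train,
                features_val[variant],
                y_val,
                space=space,
                n_iter=self.n_iter,
                seed=self.seed + vi,
                task=self.task,
            )
            self.hyperparams_[variant] = hp
            self.trials_[variant] = log
            model = train_gbm(
                features_train[variant], y_train, hp, task=self.task, seed=self.seed + vi
            )
            val_preds.append(model.predict(features_val[variant]))
        self.val_preds_ = dict(zip(VARIANTS, val_preds))
        self.weights_ = fit_ensemble_weights(
            val_preds, y_val, task=self.task, step=self.weight_step
        )
        # retrain finalists on train + validation
        y_full = np.concatenate([np.asarray(y_train, float), np.asarray(y_val, float)])
        self.models_ = {}
        for vi, variant in enumerate(VARIANTS):
            X_full = np.vstack([features_train[variant], features_val[variant]])
            self.models_[variant] = train_gbm(
                X_full, y_full, self.hyperparams_[variant], task=self.task, seed=self.seed + vi
            )
        return self

    def predict(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        if not hasattr(self, "models_"):
            raise RuntimeError("ensemble is not fitted")
        return ensemble_predict(self.models_, self.weights_, features)

    def predict_per_model(self, features: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not hasattr(self, "models_"):
            raise RuntimeError("ensemble is not fitted")
        return {v: self.models_[v].predict(features[v]) for v in VARIANTS}
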