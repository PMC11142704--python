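"""End-to-end workflow: data -> embeddings -> encoder -> features -> ensemble.

The top-level estimator :class:`MultimodalInteractionPredictor` chains the
joint encoder and the boosted-representation ensemble behind one
fit/predict surface.  :func:`run_split` executes one train/val/test cycle
and reports test metrics for the ensemble and for each individual model;
:func:`run_experiment` drives repeated splits from a structured config and
aggregates mean and standard deviation across repeats.

The test part of a split is never touched before the final evaluation:
hyperparameters and ensemble weights are selected on the validation part
only, and the manifest records the stage order.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .data import InteractionDataset, read_interaction_table
from .embeddings import EmbeddingSpec, SyntheticEmbeddingProvider
from .encoder import JointEncoderConfig, MultimodalTransformer
from .gbm import (
    DEFAULT_SPACE,
    SCALED_SPACE,
    BoostedRepresentationEnsemble,
)
from .metrics import evaluate
from .representations import extract_representations, feature_matrices
from .splits import SplitResult, SplitSpec, make_split
from .synthetic import SyntheticConfig, generate_dataset


class MultimodalInteractionPredictor(BaseEstimator):
    """Joint encoder + boosted-tree ensemble, one estimator.

    ``encoder_config`` defaults to the scaled-down architecture (suitable
    for desk-scale data); pass ``JointEncoderConfig()`` for the full-size
    published constants.  ``gbm_space="scaled"`` selects the reduced
    search-space ranges used for small runs.
    """

    def __init__(
        self,
        task: str = "regression",
        encoder_config: JointEncoderConfig | None = None,
        gbm_n_iter: int = 50,
        gbm_space: str = "scaled",
        seed: int = 0,
    ):
        self.task = task
        self.encoder_config = encoder_config
        self.gbm_n_iter = gbm_n_iter
        self.gbm_space = gbm_space
        self.seed = seed

    def _space(self):
        return SCALED_SPACE if self.gbm_space == "scaled" else DEFAULT_SPACE

    def fit(
        self,
        train: InteractionDataset,
        source,
        val: InteractionDataset,
    ) -> "MultimodalInteractionPredictor":
        cfg = self.encoder_config or JointEncoderConfig.scaled_down()
        self.encoder_ = MultimodalTransformer.from_config(cfg, task=self.task)
        self.encoder_.set_params(seed=self.seed)
        self.encoder_.fit(train, source, val)
        f_train = feature_matrices(extract_representations(self.encoder_, train, source))
        f_val = feature_matrices(extract_representations(self.encoder_, val, source))
        self.ensemble_ = BoostedRepresentationEnsemble(
            task=self.task, n_iter=self.gbm_n_iter, space=self._space(), seed=self.seed
        )
        self.ensemble_.fit(f_train, train.labels, f_val, val.labels)
        return self

    def _features(self, data: InteractionDataset, source):
        return feature_matrices(extract_representations(self.encoder_, data, source))

    def predict(self, data: InteractionDataset, source) -> np.ndarray:
        if not hasattr(self, "ensemble_"):
            raise RuntimeError("predictor is not fitted")
        return self.ensemble_.predict(self._features(data, source))

    def predict_per_model(self, data: InteractionDataset, source) -> dict[str, np.ndarray]:
        if not hasattr(self, "ensemble_"):
            raise RuntimeError("predictor is not fitted")
        return self.ensemble_.predict_per_model(self._features(data, source))


def default_provider(cfg: SyntheticConfig, d_p: int = 64, d_s: int = 32,
                     signal_scale: float = 4.0) -> SyntheticEmbeddingProvider:
    """Synthetic provider wired to the generator's signal factors."""
    return SyntheticEmbeddingProvider(
        spec=EmbeddingSpec(d_p=d_p, d_s=d_s),
        signal_tokens=cfg.signal_tokens,
        signal_scale=signal_scale,
        seed=cfg.seed,
    )


def run_split(
    data: InteractionDataset,
    split: SplitResult,
    source,
    task: str = "regression",
    encoder_config: JointEncoderConfig | None = None,
    gbm_n_iter: int = 50,
    gbm_space: str = "scaled",
    seed: int = 0,
) -> dict:
    """One full train/validate/test cycle on a prepared split.

    Returns the ensemble test report plus per-variant single-model reports
    and the raw test predictions.
    """
    train, val, test = (data.subset(split.train), data.subset(split.val), data.subset(split.test))
    model = MultimodalInteractionPredictor(
        task=task,
        encoder_config=encoder_config,
        gbm_n_iter=gbm_n_iter,
        gbm_space=gbm_space,
        seed=seed,
    )
    model.fit(train, source, val)
    y_test = np.asarray(test.labels)
    feats_test = model._features(test, source)
    pred = model.ensemble_.predict(feats_test)
    per_model = model.ensemble_.predict_per_model(feats_test)
    report = evaluate(y_test, pred, task)
    per_model_reports = {
        v: evaluate(y_test, p, task) for v, p in per_model.items()
    }
    return {
        "model": model,
        "report": report,
        "per_model_reports": per_model_reports,
        "predictions": pred,
        "per_model_predictions": per_model,
        "weights": model.ensemble_.weights_,
        "y_test": y_test,
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    provider: str
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, **info):
        self.stages.append({"stage": stage, "seconds": round(seconds, 3), **info})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "provider": self.provider,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
            default=str,
        )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as f:
            return yaml.safe_load(f)
    return dict(config)


def run_experiment(config) -> tuple[RunManifest, pd.DataFrame]:
    """Run the full workflow described by a structured config.

    Config sections: ``task``, ``seed``, ``data`` (either ``synthetic:
    {...}`` or ``table: {path, ...}``), ``provider`` (widths, signal scale),
    ``split`` (scenario, fractions, n_repeats), ``encoder`` (``scaled_down``
    flag plus overrides), ``gbm`` (``n_iter``, ``space``), optional
    ``output_dir``.  Returns the run manifest and a per-repeat metric table
    with a trailing mean/SD summary.
    """
    cfg = _load_config(config)
    task = cfg.get("task", "regression")
    seed = int(cfg.get("seed", 0))
    out_dir = Path(cfg["output_dir"]) if "output_dir" in cfg else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    data_cfg = cfg.get("data", {})
    t0 = time.perf_counter()
    if "synthetic" in data_cfg:
        syn = SyntheticConfig(task=task, seed=seed, **data_cfg["synthetic"])
        data, manifest_df = generate_dataset(syn)
    elif "table" in data_cfg:
        syn = None
        data = read_interaction_table(task=task, **data_cfg["table"])
    else:
        raise ValueError("config.data must contain 'synthetic' or 'table'")

    prov_cfg = dict(cfg.get("provider", {}))
    if syn is not None:
        provider = default_provider(syn, **prov_cfg)
    else:
        provider = SyntheticEmbeddingProvider(
            spec=EmbeddingSpec(d_p=prov_cfg.get("d_p", 64), d_s=prov_cfg.get("d_s", 32)),
            seed=seed,
        )
    manifest = RunManifest(config=cfg, seed=seed, provider=provider.name)
    manifest.record("data", time.perf_counter() - t0, n_records=len(data))

    split_cfg = dict(cfg.get("split", {}))
    spec = SplitSpec(
        scenario=split_cfg.get("scenario", "random"),
        fractions=tuple(split_cfg.get("fractions", (0.8, 0.1, 0.1))),
        n_repeats=int(split_cfg.get("n_repeats", 5)),
        seed=seed,
    )
    t0 = time.perf_counter()
    splits = make_split(data, spec)
    manifest.record("split", time.perf_counter() - t0, scenario=spec.scenario,
                    n_repeats=spec.n_repeats)

    enc_cfg_in = dict(cfg.get("encoder", {}))
    scaled = enc_cfg_in.pop("scaled_down", True)
    enc_cfg_in["seed"] = seed
    encoder_config = (
        JointEncoderConfig.scaled_down(**enc_cfg_in) if scaled else JointEncoderConfig(**enc_cfg_in)
    )
    gbm_cfg = dict(cfg.get("gbm", {}))

    rows = []
    for rep, split in enumerate(splits):
        t0 = time.perf_counter()
        result = run_split(
            data,
            split,
            provider,
            task=task,
            encoder_config=encoder_config,
            gbm_n_iter=int(gbm_cfg.get("n_iter", 50)),
            gbm_space=gbm_cfg.get("space", "scaled"),
            seed=seed + rep,
        )
        manifest.record("train_eval", time.perf_counter() - t0, repeat=rep)
        row = {"repeat": rep, **result["report"].to_dict()}
        row.update({f"w_{v}": w for v, w in zip(("cls", "pooled", "all"), result["weights"])})
        rows.append(row)
        if out_dir:
            split.to_frame().to_csv(out_dir / f"split_rep{rep}.tsv", sep="\t", index=False)

    table = pd.DataFrame(rows)
    numeric = table.drop(columns=["repeat"])
    summary = pd.DataFrame(
        [
            {"repeat": "mean", **numeric.mean().to_dict()},
            {"repeat": "sd", **numeric.std(ddof=1).to_dict()},
        ]
    )
    table = pd.concat([table, summary], ignore_index=True)
    if out_dir:
        table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        (out_dir / "manifest.json").write_text(manifest.to_json())
        manifest.outputs["metrics"] = str(out_dir / "metrics.tsv")
    return manifest, table
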