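"""Multimodal encoder: input assembly, block batching, training, inference.

The encoder concatenates ``[cls] + protein tokens + [sep] + SMILES tokens``
into one attention sequence and is trained end-to-end on interaction labels.
Defaults follow the full-size architecture (6 layers x 6 heads x head
dimension 128 = hidden 768, prediction head with one hidden layer of 32,
learning rate 1e-5, 100 epochs, batch size 12); :meth:`JointEncoderConfig.scaled_down`
gives a small configuration for desk-scale runs and tests.

Model selection is by best validation performance across epochs (parameters
are snapshotted each epoch).  For datasets too large to hold all token
embeddings in memory, entities are grouped into chunks and each epoch
iterates over all (protein-chunk, molecule-chunk) blocks, visiting every
training pair exactly once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import InteractionDataset
from .embeddings import (
    MOLECULE,
    PROTEIN,
    EmbeddingStore,
    TokenEmbeddingMatrix,
    chunk_keys,
)
from .nn import Adam, JointTransformerNet, NetDims


class CheckpointError(ValueError):
    pass


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class JointEncoderConfig:
    """Architecture and training constants of the joint encoder."""

    hidden_dim: int = 768
    num_layers: int = 6
    num_heads: int = 6
    head_dim: int = 128
    ffn_dim: int | None = None  # defaults to 4 x hidden_dim
    head_hidden_dim: int = 32
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 12
    max_grad_norm: float | None = 1.0
    use_positional_embeddings: bool = False
    selection_metric: str = "loss"  # epoch selection on the validation set
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim != self.num_heads * self.head_dim:
            raise ValueError(
                f"hidden_dim ({self.hidden_dim}) must equal num_heads x head_dim "
                f"({self.num_heads} x {self.head_dim})"
            )

    @property
    def resolved_ffn_dim(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim

    @classmethod
    def scaled_down(cls, **overrides) -> "JointEncoderConfig":
        """Small configuration for desk-scale experiments and tests.

        2 layers, hidden 64 (2 heads x 32), 30 epochs, batch size 24.  The
        learning rate is raised to 1e-3: the full-size rate of 1e-5 is tuned
        to 100-epoch runs on tens of thousands of pairs and leaves a small
        fresh model badly underfit within 30 epochs.
        """
        base = dict(
            hidden_dim=64, num_layers=2, num_heads=2, head_dim=32,
            epochs=30, learning_rate=1e-3, batch_size=24,
        )
        base.update(overrides)
        return cls(**base)

    # IC50 pretraining constants from the published setup
    PRETRAIN_LEARNING_RATE = 1.5e-5
    PRETRAIN_BATCH_SIZE = 192


@dataclass(frozen=True)
class AssembledInput:
    """One assembled attention sequence: cls + protein + sep + molecule."""

    matrix: np.ndarray  # (1 + n_prot + 1 + n_mol, hidden_dim)
    attention_mask: np.ndarray  # (rows,) of {0,1}
    segment_labels: tuple[str, ...]  # "cls" | "protein" | "sep" | "molecule"


def assemble_input(
    prot: TokenEmbeddingMatrix,
    mol: TokenEmbeddingMatrix,
    pools: Mapping[str, np.ndarray],
    cfg: JointEncoderConfig,
) -> AssembledInput:
    """Map raw token matrices into the joint hidden space and assemble rows.

    ``pools`` holds the pooling-layer parameters ``pool_p/W``, ``pool_p/b``,
    ``pool_m/W``, ``pool_m/b``.  Protein and molecule rows pass through their
    ReLU pooling layer; the cls row is all ones and the sep row all zeros in
    the hidden space (they bypass pooling).
    """
    H = cfg.hidden_dim
    if prot.width != pools["pool_p/W"].shape[0]:
        raise ValueError(
            f"protein width {prot.width} != pooling fan-in {pools['pool_p/W'].shape[0]}"
        )
    if mol.width != pools["pool_m/W"].shape[0]:
        raise ValueError(
            f"molecule width {mol.width} != pooling fan-in {pools['pool_m/W'].shape[0]}"
        )
    hp = np.maximum(prot.matrix @ pools["pool_p/W"] + pools["pool_p/b"], 0.0)
    hm = np.maximum(mol.matrix @ pools["pool_m/W"] + pools["pool_m/b"], 0.0)
    rows = np.concatenate([np.ones((1, H)), hp, np.zeros((1, H)), hm], axis=0)
    labels = ("cls",) + ("protein",) * hp.shape[0] + ("sep",) + ("molecule",) * hm.shape[0]
    return AssembledInput(
        matrix=rows,
        attention_mask=np.ones(rows.shape[0], dtype=np.int8),
        segment_labels=labels,
    )


def plan_subset_batches(
    protein_ids: Sequence[str],
    molecule_ids: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    chunk_size: int = 1000,
) -> list[dict]:
    """Partition training pairs into (protein-chunk, molecule-chunk) blocks.

    Entities are chunked consecutively; every pair lands in exactly the one
    block holding both its protein chunk and its molecule chunk, so a full
    sweep over the plan covers each pair exactly once while only one chunk
    of each modality needs to be in memory.
    """
    p_chunks = chunk_keys(list(protein_ids), chunk_size)
    m_chunks = chunk_keys(list(molecule_ids), chunk_size)
    p_where = {pid: ci for ci, chunk in enumerate(p_chunks) for pid in chunk}
    m_where = {mid: ci for ci, chunk in enumerate(m_chunks) for mid in chunk}
    blocks: dict[tuple[int, int], list[int]] = {
        (pi, mi): [] for pi in range(len(p_chunks)) for mi in range(len(m_chunks))
    }
    for idx, (pid, mid) in enumerate(pairs):
        if pid not in p_where:
            raise PlanError(f"pair references unknown protein id {pid!r}")
        if mid not in m_where:
            raise PlanError(f"pair references unknown molecule id {mid!r}")
        blocks[(p_where[pid], m_where[mid])].append(idx)
    return [
        {
            "protein_chunk": pi,
            "molecule_chunk": mi,
            "protein_ids": p_chunks[pi],
            "molecule_ids": m_chunks[mi],
            "pair_indices": idxs,
        }
        for (pi, mi), idxs in blocks.items()
    ]


# --------------------------------------------------------------------------- #
# batching helpers


def _pad_batch(mats: Sequence[np.ndarray], dtype) -> tuple[np.ndarray, np.ndarray]:
    lmax = max(m.shape[0] for m in mats)
    B, d = len(mats), mats[0].shape[1]
    out = np.zeros((B, lmax, d), dtype=dtype)
    mask = np.zeros((B, lmax), dtype=dtype)
    for i, m in enumerate(mats):
        out[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return out, mask


class _MatrixSource:
    """Uniform access to token matrices from a store or a provider."""

    def __init__(self, source, dataset: InteractionDataset):
        self.source = source
        self._cache: dict[tuple[str, str], np.ndarray] = {}
        self.seq_by_pid = {r.protein_id: r.sequence for r in dataset}

    def protein(self, pid: str) -> np.ndarray:
        key = (PROTEIN, pid)
        if key not in self._cache:
            if isinstance(self.source, EmbeddingStore):
                m = self.source.get(PROTEIN, pid).matrix
            else:
                m = self.source.embed_text(self.seq_by_pid[pid], PROTEIN).matrix
            self._cache[key] = m
        return self._cache[key]

    def molecule(self, smiles: str) -> np.ndarray:
        key = (MOLECULE, smiles)
        if key not in self._cache:
            if isinstance(self.source, EmbeddingStore):
                m = self.source.get(MOLECULE, smiles).matrix
            else:
                m = self.source.embed_text(smiles, MOLECULE).matrix
            self._cache[key] = m
        return self._cache[key]


class MultimodalTransformer(BaseEstimator):
    """Joint protein-molecule attention encoder, scikit-learn style.

    Parameters mirror :class:`JointEncoderConfig`.  ``fit`` consumes an
    :class:`InteractionDataset` plus an embedding source (an
    :class:`EmbeddingStore` or a provider with ``embed_text``) and snapshots
    the epoch with the best validation loss.

    Fitted attributes
    -----------------
    params_ : dict of parameter arrays of the best epoch
    history_ : per-epoch train/validation losses (DataFrame)
    best_epoch_ : int
    dims_ : NetDims
    """

    def __init__(
        self,
        hidden_dim: int = 768,
        num_layers: int = 6,
        num_heads: int = 6,
        head_dim: int = 128,
        ffn_dim: int | None = None,
        head_hidden_dim: int = 32,
        learning_rate: float = 1e-5,
        epochs: int = 100,
        batch_size: int = 12,
        max_grad_norm: float | None = 1.0,
        use_positional_embeddings: bool = False,
        task: str = "regression",
        chunk_size: int = 1000,
        seed: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.head_dim = head_dim
        self.ffn_dim = ffn_dim
        self.head_hidden_dim = head_hidden_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.max_grad_norm = max_grad_norm
        self.use_positional_embeddings = use_positional_embeddings
        self.task = task
        self.chunk_size = chunk_size
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: JointEncoderConfig, task: str = "regression", **kw):
        return cls(
            hidden_dim=cfg.hidden_dim,
            num_layers=cfg.num_layers,
            num_heads=cfg.num_heads,
            head_dim=cfg.head_dim,
            ffn_dim=cfg.ffn_dim,
            head_hidden_dim=cfg.head_hidden_dim,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            max_grad_norm=cfg.max_grad_norm,
            use_positional_embeddings=cfg.use_positional_embeddings,
            seed=cfg.seed,
            task=task,
            **kw,
        )

    # ------------------------------------------------------------------- fit

    def _make_dims(self, d_p: int, d_s: int) -> NetDims:
        return NetDims(
            d_p=d_p,
            d_s=d_s,
            hidden_dim=self.hidden_dim,
            num_layers=self.num_layers,
            num_heads=self.num_heads,
            head_dim=self.head_dim,
            ffn_dim=self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim,
            head_hidden_dim=self.head_hidden_dim,
        )

    def _build_net(self, d_p: int, d_s: int, warm_start=None) -> JointTransformerNet:
        dims = self._make_dims(d_p, d_s)
        net = JointTransformerNet(dims, task=self.task, seed=self.seed)
        net.use_positional = self.use_positional_embeddings
        if warm_start is not None:
            params, meta = _load_checkpoint_data(warm_start)
            _check_warm_start(net.params, params, meta, self.task)
            for k in net.params:
                if k in params and params[k].shape == net.params[k].shape:
                    net.params[k] = params[k].astype(net.dtype)
        return net

    def fit(
        self,
        train: InteractionDataset,
        source,
        val: InteractionDataset,
        warm_start=None,
    ) -> "MultimodalTransformer":
        if len(val) == 0:
            raise ValueError("validation set must be non-empty")
        if train.task != self.task:
            raise ValueError(f"dataset task {train.task!r} != estimator task {self.task!r}")
        mats = _MatrixSource(source, train)
        mats.seq_by_pid.update({r.protein_id: r.sequence for r in val})
        # probe widths
        d_p = mats.protein(train[0].protein_id).shape[1]
        d_s = mats.molecule(train[0].smiles).shape[1]
        net = self._build_net(d_p, d_s, warm_start)
        opt = Adam(net.params, lr=self.learning_rate, max_grad_norm=self.max_grad_norm)
        rng = np.random.default_rng(self.seed)

        pairs = [(r.protein_id, r.smiles) for r in train]
        uniq_p = list(dict.fromkeys(p for p, _ in pairs))
        uniq_m = list(dict.fromkeys(m for _, m in pairs))
        plan = plan_subset_batches(uniq_p, uniq_m, pairs, self.chunk_size)
        y_train = np.asarray(train.labels, dtype=np.float64)

        history = []
        best = (np.inf, None, -1)  # (val loss, params, epoch)
        if self.epochs == 0 and warm_start is not None:
            best = (np.nan, net.clone_params(), -1)
        for epoch in range(self.epochs):
            train_losses, train_counts = [], []
            block_order = rng.permutation(len(plan))
            for bi in block_order:
                block = plan[bi]
                idxs = block["pair_indices"]
                if not idxs:
                    continue
                # sort by total length to limit padding, then shuffle batches
                idxs = sorted(
                    idxs,
                    key=lambda i: mats.protein(train[i].protein_id).shape[0]
                    + mats.molecule(train[i].smiles).shape[0],
                )
                batches = [
                    idxs[j : j + self.batch_size]
                    for j in range(0, len(idxs), self.batch_size)
                ]
                for b in rng.permutation(len(batches)):
                    batch = batches[b]
                    P, pm = _pad_batch(
                        [mats.protein(train[i].protein_id) for i in batch], net.dtype
                    )
                    M, mm = _pad_batch(
                        [mats.molecule(train[i].smiles) for i in batch], net.dtype
                    )
                    loss, grads = net.loss_and_grads(P, pm, M, mm, y_train[batch])
                    opt.step(net.params, grads)
                    train_losses.append(loss * len(batch))
                    train_counts.append(len(batch))
            train_loss = float(np.sum(train_losses) / np.sum(train_counts))
            val_loss = self._eval_loss(net, val, mats)
            history.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if val_loss < best[0]:
                best = (val_loss, net.clone_params(), epoch)

        if best[1] is None:
            best = (np.nan, net.clone_params(), -1)
        self.params_ = best[1]
        self.best_epoch_ = best[2]
        self.history_ = pd.DataFrame(history)
        self.dims_ = net.dims
        self._net = JointTransformerNet(
            net.dims, task=self.task, params=self.params_
        )
        self._net.use_positional = self.use_positional_embeddings
        return self

    def _eval_loss(self, net, data: InteractionDataset, mats: "_MatrixSource") -> float:
        y = np.asarray(data.labels, dtype=np.float64)
        preds = self._predict_with(net, data, mats)
        if self.task == "regression":
            return float(np.mean((preds - y) ** 2))
        eps = 1e-12
        p = np.clip(preds, eps, 1 - eps)
        return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))

    def _predict_with(self, net, data, mats, batch_size: int = 64,
                      return_cls: bool = False):
        preds = np.empty(len(data))
        cls_out = np.empty((len(data), self.hidden_dim)) if return_cls else None
        order = sorted(
            range(len(data)),
            key=lambda i: mats.protein(data[i].protein_id).shape[0]
            + mats.molecule(data[i].smiles).shape[0],
        )
        for j in range(0, len(order), batch_size):
            batch = order[j : j + batch_size]
            P, pm = _pad_batch([mats.protein(data[i].protein_id) for i in batch], net.dtype)
            M, mm = _pad_batch([mats.molecule(data[i].smiles) for i in batch], net.dtype)
            pred, cls, _ = net.forward(P, pm, M, mm)
            preds[batch] = pred
            if return_cls:
                cls_out[batch] = cls
        return (preds, cls_out) if return_cls else preds

    # -------------------------------------------------------------- inference

    def predict(self, data: InteractionDataset, source) -> np.ndarray:
        """Direct encoder prediction (evaluation mode, deterministic)."""
        self._check_fitted()
        mats = _MatrixSource(source, data)
        return self._predict_with(self._net, data, mats)

    def transform(self, data: InteractionDataset, source) -> np.ndarray:
        """Updated cls vectors (rows aligned with ``data``)."""
        self._check_fitted()
        mats = _MatrixSource(source, data)
        _, cls = self._predict_with(self._net, data, mats, return_cls=True)
        return cls

    def forward_one(
        self, prot: TokenEmbeddingMatrix, mol: TokenEmbeddingMatrix
    ) -> tuple[float, np.ndarray]:
        """Single-example forward pass: (prediction, cls vector)."""
        self._check_fitted()
        net = self._net
        P = prot.matrix[None].astype(net.dtype)
        M = mol.matrix[None].astype(net.dtype)
        pm = np.ones(P.shape[:2], dtype=net.dtype)
        mm = np.ones(M.shape[:2], dtype=net.dtype)
        pred, cls, _ = net.forward(P, pm, M, mm)
        return float(pred[0]), cls[0]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    # ------------------------------------------------------------- checkpoints

    def save_checkpoint(self, path: str | Path) -> None:
        self._check_fitted()
        meta = {
            "task": self.task,
            "config": {
                "hidden_dim": self.hidden_dim,
                "num_layers": self.num_layers,
                "num_heads": self.num_heads,
                "head_dim": self.head_dim,
                "head_hidden_dim": self.head_hidden_dim,
            },
            "best_epoch": int(self.best_epoch_),
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params_)

    @staticmethod
    def load_params(path: str | Path) -> dict[str, np.ndarray]:
        params, _ = _load_checkpoint_data(path)
        return params


def _load_checkpoint_data(source) -> tuple[dict[str, np.ndarray], dict]:
    if isinstance(source, (str, Path)):
        with np.load(source, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"])) if "__meta__" in z else {}
            params = {k: z[k] for k in z.files if k != "__meta__"}
        return params, meta
    if isinstance(source, Mapping):
        return dict(source), {}
    raise CheckpointError(f"unsupported checkpoint source {type(source)!r}")


_HEAD_KEYS = ("head1/W", "head1/b", "head2/W", "head2/b")


def _check_warm_start(current, loaded, meta, task):
    """Shapes must match exactly, except the head may be reinitialised when
    the checkpoint was trained for a different task kind."""
    task_changed = bool(meta) and meta.get("task") not in (None, task)
    mismatched = []
    for k, v in current.items():
        if k not in loaded:
            if k in _HEAD_KEYS and task_changed:
                continue
            mismatched.append(f"{k}: missing from checkpoint")
        elif loaded[k].shape != v.shape:
            if k in _HEAD_KEYS and task_changed:
                loaded.pop(k)
                continue
            mismatched.append(f"{k}: checkpoint {loaded[k].shape} vs model {v.shape}")
    if task_changed:
        for k in _HEAD_KEYS:
            loaded.pop(k, None)
    if mismatched:
        raise CheckpointError("warm-start shape mismatch: " + "; ".join(mismatched))
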