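"""Numerical core of the multimodal attention encoder.

A BERT-style post-norm transformer implemented directly on NumPy arrays with
hand-written backpropagation (verified against finite differences in the test
suite).  The model consumes batches of pre-computed per-token embeddings:

* protein rows are mapped from width ``d_p`` to the hidden dimension by a
  single ReLU-activated pooling layer, molecule rows likewise from ``d_s``;
* the assembled sequence is ``[cls] + protein tokens + [sep] + molecule
  tokens`` where the cls input row is all ones and the sep row all zeros;
* after the attention layers the updated cls row feeds a one-hidden-layer
  (ReLU, width ``head_hidden_dim``) prediction head — linear output for
  regression, sigmoid for binary classification.

Padding uses an additive attention mask; padded key positions receive a
large negative score, so they carry exactly zero attention weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
NEG_INF = -1e9
_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _proj(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(B, L, i) @ (i, j) + b through a single 2D GEMM."""
    B, L, _ = x.shape
    return (x.reshape(B * L, -1) @ W + b).reshape(B, L, -1)


def _bl_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Contract (B, L, i) x (B, L, j) -> (i, j) through BLAS."""
    return a.reshape(-1, a.shape[-1]).T @ b.reshape(-1, b.shape[-1])


_GELU_C = math.sqrt(2.0 / math.pi)


def _proj_bwd(d: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(B, L, j) @ (j, i) through a single 2D GEMM."""
    B, L, _ = d.shape
    return (d.reshape(B * L, -1) @ W.T).reshape(B, L, -1)


def gelu(x: np.ndarray) -> np.ndarray:
    """Tanh-form GELU (the BERT approximation)."""
    return 0.5 * x * (1.0 + np.tanh(_GELU_C * (x + 0.044715 * (x * x * x))))


def gelu_with_cache(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.tanh(_GELU_C * (x + 0.044715 * (x * x * x)))
    return 0.5 * x * (1.0 + t), t


def gelu_grad(x: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """Derivative of the tanh-form GELU; reuses the cached tanh if given."""
    if t is None:
        t = np.tanh(_GELU_C * (x + 0.044715 * (x * x * x)))
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * _GELU_C * (1.0 + 3 * 0.044715 * x * x)


def sinusoidal_positions(length: int, width: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(width)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / width)
    out = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return out


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class NetDims:
    """Shape constants of one encoder instance."""

    d_p: int
    d_s: int
    hidden_dim: int
    num_layers: int
    num_heads: int
    head_dim: int
    ffn_dim: int
    head_hidden_dim: int

    def __post_init__(self):
        if self.hidden_dim != self.num_heads * self.head_dim:
            raise ValueError(
                f"hidden_dim ({self.hidden_dim}) must equal num_heads x head_dim "
                f"({self.num_heads} x {self.head_dim})"
            )


def init_params(dims: NetDims, rng: np.random.Generator, dtype=np.float32) -> dict[str, np.ndarray]:
    """Scaled-normal initialisation of all trainable tensors."""
    H, F = dims.hidden_dim, dims.ffn_dim
    p: dict[str, np.ndarray] = {}

    def lin(name: str, fan_in: int, fan_out: int):
        p[f"{name}/W"] = rng.normal(0.0, 1.0 / math.sqrt(fan_in), (fan_in, fan_out))
        p[f"{name}/b"] = np.zeros(fan_out)

    lin("pool_p", dims.d_p, H)
    lin("pool_m", dims.d_s, H)
    for i in range(dims.num_layers):
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            lin(f"L{i}/{nm}", H, H)
        p[f"L{i}/ln1/g"] = np.ones(H)
        p[f"L{i}/ln1/b"] = np.zeros(H)
        lin(f"L{i}/ffn1", H, F)
        lin(f"L{i}/ffn2", F, H)
        p[f"L{i}/ln2/g"] = np.ones(H)
        p[f"L{i}/ln2/b"] = np.zeros(H)
    lin("head1", H, dims.head_hidden_dim)
    lin("head2", dims.head_hidden_dim, 1)
    return {k: v.astype(dtype) for k, v in p.items()}


LN_EPS = 1e-5


def _layer_norm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layer_norm_bwd(dy, cache):
    xhat, inv, g = cache
    H = xhat.shape[-1]
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = (
        inv
        / H
        * (
            H * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )
    )
    return dx, dg, db


class JointTransformerNet:
    """Parameter container plus forward / loss-and-gradient passes.

    ``task`` decides the output nonlinearity and the training loss:
    mean squared error for ``regression``, binary cross-entropy (computed on
    logits for stability) for ``binary_classification``.
    """

    def __init__(
        self,
        dims: NetDims,
        task: str = "regression",
        seed: int = 0,
        dtype=np.float32,
        params: Mapping[str, np.ndarray] | None = None,
    ):
        self.dims = dims
        self.task = task
        self.dtype = dtype
        if params is not None:
            self.params = {k: np.asarray(v, dtype=dtype) for k, v in params.items()}
        else:
            self.params = init_params(dims, np.random.default_rng(seed), dtype)

    # ------------------------------------------------------------------ forward

    def _encode(self, prot, p_mask, mol, m_mask, collect_cache: bool):
        """Run pooling layers + attention stack.

        prot: (B, Lp, d_p); p_mask: (B, Lp) in {0,1}; mol: (B, Ls, d_s).
        Returns (x_final, mask, cache).
        """
        P = self.params
        B, Lp, _ = prot.shape
        Ls = mol.shape[1]
        D = self.dims
        nh, hd = D.num_heads, D.head_dim

        zp = _proj(prot, P["pool_p/W"], P["pool_p/b"])
        hp = np.maximum(zp, 0.0) * p_mask[..., None]
        zm = _proj(mol, P["pool_m/W"], P["pool_m/b"])
        hm = np.maximum(zm, 0.0) * m_mask[..., None]

        ones = np.ones((B, 1, D.hidden_dim), dtype=hp.dtype)
        zeros = np.zeros((B, 1, D.hidden_dim), dtype=hp.dtype)
        x = np.concatenate([ones, hp, zeros, hm], axis=1)  # (B, L, H)
        if getattr(self, "use_positional", False):
            # optional sinusoidal positions; off by default since the
            # upstream token embeddings are already position-aware
            x = x + sinusoidal_positions(x.shape[1], D.hidden_dim).astype(x.dtype)
        mask = np.concatenate(
            [np.ones((B, 1)), p_mask, np.ones((B, 1)), m_mask], axis=1
        ).astype(x.dtype)
        addmask = np.where(mask[:, None, None, :] > 0, 0.0, NEG_INF).astype(x.dtype)

        cache = {"zp": zp, "zm": zm, "prot": prot, "mol": mol,
                 "p_mask": p_mask, "m_mask": m_mask, "mask": mask} if collect_cache else None
        layer_caches = []
        scale = 1.0 / math.sqrt(hd)

        def split(t):  # (B, L, H) -> (B, nh, L, hd)
            return t.reshape(B, -1, nh, hd).transpose(0, 2, 1, 3)

        def merge(t):  # (B, nh, L, hd) -> (B, L, H)
            return t.transpose(0, 2, 1, 3).reshape(B, -1, nh * hd)

        for i in range(D.num_layers):
            x_in = x
            q = _proj(x, P[f"L{i}/Wq/W"], P[f"L{i}/Wq/b"])
            k = _proj(x, P[f"L{i}/Wk/W"], P[f"L{i}/Wk/b"])
            v = _proj(x, P[f"L{i}/Wv/W"], P[f"L{i}/Wv/b"])
            qh, kh, vh = split(q), split(k), split(v)
            s = np.matmul(qh, kh.transpose(0, 1, 3, 2)) * scale + addmask
            s -= s.max(axis=-1, keepdims=True)
            e = np.exp(s)
            a = e / e.sum(axis=-1, keepdims=True)
            oh = np.matmul(a, vh)
            o = merge(oh)
            att = _proj(o, P[f"L{i}/Wo/W"], P[f"L{i}/Wo/b"])
            if not np.isfinite(att).all():
                raise FloatingPointError(f"non-finite activations in attention layer {i}")
            x1, ln1_cache = _layer_norm_fwd(x_in + att, P[f"L{i}/ln1/g"], P[f"L{i}/ln1/b"])
            z1 = _proj(x1, P[f"L{i}/ffn1/W"], P[f"L{i}/ffn1/b"])
            g1, t1 = gelu_with_cache(z1)
            f = _proj(g1, P[f"L{i}/ffn2/W"], P[f"L{i}/ffn2/b"])
            if not np.isfinite(f).all():
                raise FloatingPointError(f"non-finite activations in FFN layer {i}")
            x, ln2_cache = _layer_norm_fwd(x1 + f, P[f"L{i}/ln2/g"], P[f"L{i}/ln2/b"])
            if collect_cache:
                layer_caches.append(
                    {"x_in": x_in, "qh": qh, "kh": kh, "vh": vh, "a": a, "o": o,
                     "ln1": ln1_cache, "x1": x1, "z1": z1, "t1": t1, "g1": g1, "ln2": ln2_cache}
                )
        if collect_cache:
            cache["layers"] = layer_caches
        return x, mask, cache

    def forward(self, prot, p_mask, mol, m_mask, collect_cache: bool = False):
        """Return (prediction, cls_vector, cache).

        ``prediction`` is the regression output or the classification
        probability; the logit is available in the cache.
        """
        P = self.params
        x, mask, cache = self._encode(prot, p_mask, mol, m_mask, collect_cache)
        cls = x[:, 0, :]
        z_h = cls @ P["head1/W"] + P["head1/b"]
        h = np.maximum(z_h, 0.0)
        logit = (h @ P["head2/W"] + P["head2/b"])[:, 0]
        pred = sigmoid(logit) if self.task == "binary_classification" else logit
        if collect_cache:
            cache.update({"x_final": x, "cls": cls, "z_h": z_h, "h": h, "logit": logit})
        return pred, cls, cache

    # ----------------------------------------------------------------- backward

    def loss_and_grads(self, prot, p_mask, mol, m_mask, y):
        """Mean loss over the batch plus gradients for every parameter."""
        P = self.params
        y = np.asarray(y, dtype=self.dtype)
        pred, _, cache = self.forward(prot, p_mask, mol, m_mask, collect_cache=True)
        B = y.shape[0]
        logit = cache["logit"]
        if self.task == "regression":
            loss = float(np.mean((logit - y) ** 2))
            dlogit = 2.0 * (logit - y) / B
        else:
            # BCE on logits: softplus(z) - y*z
            loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))
            dlogit = (sigmoid(logit) - y) / B

        g = {k: np.zeros_like(v) for k, v in P.items()}
        D = self.dims
        nh, hd = D.num_heads, D.head_dim
        scale = 1.0 / math.sqrt(hd)

        # head
        h, z_h, cls = cache["h"], cache["z_h"], cache["cls"]
        dlogit2 = dlogit[:, None]
        g["head2/W"] += h.T @ dlogit2
        g["head2/b"] += dlogit2.sum(axis=0)
        dh = dlogit2 @ P["head2/W"].T
        dz_h = dh * (z_h > 0)
        g["head1/W"] += cls.T @ dz_h
        g["head1/b"] += dz_h.sum(axis=0)
        dcls = dz_h @ P["head1/W"].T

        dx = np.zeros_like(cache["x_final"])
        dx[:, 0, :] = dcls

        Bsz = dx.shape[0]

        def split(t):
            return t.reshape(Bsz, -1, nh, hd).transpose(0, 2, 1, 3)

        def merge(t):
            return t.transpose(0, 2, 1, 3).reshape(Bsz, -1, nh * hd)

        for i in reversed(range(D.num_layers)):
            c = cache["layers"][i]
            # ln2
            dsum2, dg2, db2 = _layer_norm_bwd(dx, c["ln2"])
            g[f"L{i}/ln2/g"] += dg2
            g[f"L{i}/ln2/b"] += db2
            dx1 = dsum2.copy()
            df = dsum2
            # ffn
            g[f"L{i}/ffn2/W"] += _bl_matmul(c["g1"], df)
            g[f"L{i}/ffn2/b"] += df.sum(axis=(0, 1))
            dg1 = _proj_bwd(df, P[f"L{i}/ffn2/W"])
            dz1 = dg1 * gelu_grad(c["z1"], c["t1"])
            g[f"L{i}/ffn1/W"] += _bl_matmul(c["x1"], dz1)
            g[f"L{i}/ffn1/b"] += dz1.sum(axis=(0, 1))
            dx1 += _proj_bwd(dz1, P[f"L{i}/ffn1/W"])
            # ln1
            dsum1, dg1_, db1_ = _layer_norm_bwd(dx1, c["ln1"])
            g[f"L{i}/ln1/g"] += dg1_
            g[f"L{i}/ln1/b"] += db1_
            dx_in = dsum1.copy()
            datt = dsum1
            # output projection
            g[f"L{i}/Wo/W"] += _bl_matmul(c["o"], datt)
            g[f"L{i}/Wo/b"] += datt.sum(axis=(0, 1))
            do = _proj_bwd(datt, P[f"L{i}/Wo/W"])
            doh = split(do)
            da = np.matmul(doh, c["vh"].transpose(0, 1, 3, 2))
            dvh = np.matmul(c["a"].transpose(0, 1, 3, 2), doh)
            # softmax backward
            a = c["a"]
            ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
            dqh = np.matmul(ds, c["kh"]) * scale
            dkh = np.matmul(ds.transpose(0, 1, 3, 2), c["qh"]) * scale
            dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
            x_in = c["x_in"]
            for nm, dt in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
                g[f"L{i}/{nm}/W"] += _bl_matmul(x_in, dt)
                g[f"L{i}/{nm}/b"] += dt.sum(axis=(0, 1))
                dx_in += _proj_bwd(dt, P[f"L{i}/{nm}/W"])
            dx = dx_in

        # split the assembled-sequence gradient back into segments
        Lp = cache["prot"].shape[1]
        dhp = dx[:, 1 : 1 + Lp, :]
        dhm = dx[:, 2 + Lp :, :]
        # pooling layers (masked ReLU)
        dzp = dhp * cache["p_mask"][..., None] * (cache["zp"] > 0)
        g["pool_p/W"] += _bl_matmul(cache["prot"], dzp)
        g["pool_p/b"] += dzp.sum(axis=(0, 1))
        dzm = dhm * cache["m_mask"][..., None] * (cache["zm"] > 0)
        g["pool_m/W"] += _bl_matmul(cache["mol"], dzm)
        g["pool_m/b"] += dzm.sum(axis=(0, 1))
        return loss, g

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 max_grad_norm: float | None = 1.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        if self.max_grad_norm is not None:
            total = math.sqrt(sum(float(np.sum(gr.astype(np.float64) ** 2)) for gr in grads.values()))
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
                grads = {k: gr * scale for k, gr in grads.items()}
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
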