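"""Per-record feature blocks: joint cls vector + mean-pooled modality vectors.

Each record yields three blocks: the updated cls vector from the trained
joint encoder (task-specific, width = encoder hidden dimension), the
element-wise mean of the protein's per-token embeddings (width d_p), and the
element-wise mean of the molecule's per-token embeddings (width d_s).  The
three feature variants fed to the boosted models are the cls block alone,
the concatenated pooled pair, and all three concatenated in the fixed order
cls | protein | molecule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import InteractionDataset
from .encoder import MultimodalTransformer, _MatrixSource

VARIANT_ORDER = ("cls", "protein_mean", "molecule_mean")


@dataclass(frozen=True)
class RepresentationBundle:
    cls: np.ndarray
    protein_mean: np.ndarray
    molecule_mean: np.ndarray

    def __post_init__(self):
        for name in ("cls", "protein_mean", "molecule_mean"):
            v = getattr(self, name)
            if v.ndim != 1:
                raise ValueError(f"{name} must be a vector")
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite entries in {name}")


def extract_representations(
    model: MultimodalTransformer,
    data: InteractionDataset,
    source,
) -> list[RepresentationBundle]:
    """One bundle per record, aligned with record order.

    The cls vector is computed in evaluation mode from the trained encoder;
    the pooled vectors depend only on the raw per-token embeddings and are
    identical for records sharing a protein or molecule.
    """
    mats = _MatrixSource(source, data)
    cls_rows = model.transform(data, source)
    bundles = []
    for i, r in enumerate(data):
        p_mean = mats.protein(r.protein_id).mean(axis=0)
        m_mean = mats.molecule(r.smiles).mean(axis=0)
        bundles.append(
            RepresentationBundle(cls=cls_rows[i], protein_mean=p_mean, molecule_mean=m_mean)
        )
    return bundles


def assemble_features(
    bundles: Sequence[RepresentationBundle],
    variant: str,
) -> np.ndarray:
    """Stack bundles into the feature matrix for one model variant.

    Widths at the published embedding dimensions: 768 (``cls_only``),
    1280 + 600 = 1880 (``pooled_pair``), 2648 (``all``).
    """
    if not bundles:
        raise ValueError("no bundles")
    for name in ("cls", "protein_mean", "molecule_mean"):
        widths = {getattr(b, name).shape[0] for b in bundles}
        if len(widths) != 1:
            raise ValueError(f"inconsistent {name} widths across bundles: {sorted(widths)}")
    if variant == "cls_only":
        return np.stack([b.cls for b in bundles])
    if variant == "pooled_pair":
        return np.stack([np.concatenate([b.protein_mean, b.molecule_mean]) for b in bundles])
    if variant == "all":
        return np.stack(
            [np.concatenate([b.cls, b.protein_mean, b.molecule_mean]) for b in bundles]
        )
    raise ValueError(f"unknown variant {variant!r}")


def feature_matrices(
    bundles: Sequence[RepresentationBundle],
) -> dict[str, np.ndarray]:
    """All three variants at once, keyed for the boosted ensemble."""
    return {v: assemble_features(bundles, v) for v in ("cls_only", "pooled_pair", "all")}
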