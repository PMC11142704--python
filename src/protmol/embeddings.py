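"""Token embedding providers and the chunked embedding store.

Proteins and SMILES strings are tokenized and mapped to per-token embedding
matrices by a *provider*.  Real protein/chemical language models (per-residue
protein embeddings of width 1280, SMILES token embeddings of width 600) can
be plugged in behind the :class:`EmbeddingProvider` contract; the built-in
:class:`SyntheticEmbeddingProvider` is a deterministic stand-in that needs no
downloads and is the default for testing and synthetic benchmarks.

Provider embeddings are frozen: they are computed once per entity and stored
in a chunked single-file container (:class:`EmbeddingStore`) so that at most
one chunk per modality needs to be resident in memory during training.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Protocol, Sequence

import h5py
import numpy as np

PROTEIN = "protein"
MOLECULE = "molecule"
MODALITIES = (PROTEIN, MOLECULE)

# Standard SMILES token regex: bracket atoms, two-letter halogens, aromatic
# atoms, bonds, branches, ring-closure digits and %nn ring labels.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)


class TokenizationError(ValueError):
    pass


class EmbeddingError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding widths and token-length limits.

    Defaults match the published protein / chemical language model widths
    (1280 and 600) and the sequence limits (first 1024 amino acids, first
    256 SMILES tokens).
    """

    d_p: int = 1280
    d_s: int = 600
    max_protein_tokens: int = 1024
    max_smiles_tokens: int = 256

    def __post_init__(self):
        for name in ("d_p", "d_s", "max_protein_tokens", "max_smiles_tokens"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")

    def width(self, modality: str) -> int:
        return {PROTEIN: self.d_p, MOLECULE: self.d_s}[modality]

    def max_tokens(self, modality: str) -> int:
        return {PROTEIN: self.max_protein_tokens, MOLECULE: self.max_smiles_tokens}[modality]


@dataclass(frozen=True)
class TokenEmbeddingMatrix:
    """Per-token embedding rows for one protein or one molecule."""

    tokens: tuple[str, ...]
    matrix: np.ndarray  # shape (len(tokens), width)

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.tokens):
            raise ValueError("matrix rows must match token count")
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite entries in embedding matrix")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class PooledVector:
    values: np.ndarray
    modality: str


def tokenize_smiles(smiles: str, spec: EmbeddingSpec | None = None) -> list[str]:
    """Split a SMILES string into standard tokens, keeping the first 256.

    The tokens concatenate back to a prefix of the input (the whole input
    when no truncation occurs).
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    spec = spec or EmbeddingSpec()
    tokens = SMILES_TOKEN_RE.findall(smiles)
    if not tokens:
        raise TokenizationError(f"no tokens found in SMILES {smiles!r}")
    if "".join(tokens) != smiles:
        raise TokenizationError(f"untokenizable characters in SMILES {smiles!r}")
    return tokens[: spec.max_smiles_tokens]


def mean_pool(m: TokenEmbeddingMatrix, modality: str = PROTEIN) -> PooledVector:
    """Element-wise mean across token embedding rows."""
    if m.matrix.shape[0] == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    return PooledVector(values=m.matrix.mean(axis=0), modality=modality)


class EmbeddingProvider(Protocol):
    """Contract every embedding backend fulfils."""

    spec: EmbeddingSpec

    @property
    def name(self) -> str: ...

    def tokenize(self, text: str, modality: str) -> list[str]: ...

    def embed(self, tokens: Sequence[str], modality: str) -> TokenEmbeddingMatrix: ...


def embed_tokens(
    provider: "EmbeddingProvider", tokens: Sequence[str], modality: str
) -> TokenEmbeddingMatrix:
    """Embed a token list with a provider (thin functional wrapper)."""
    if modality not in MODALITIES:
        raise EmbeddingError(f"unknown modality {modality!r}")
    return provider.embed(tokens, modality)


def _hash_seed(*parts: object) -> int:
    digest = hashlib.blake2b("|".join(map(str, parts)).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little")


class SyntheticEmbeddingProvider:
    """Deterministic pseudo-random embeddings with a decodable signal block.

    Each token's embedding is a fixed unit-variance pseudo-random vector
    derived from a hash of (modality, token, seed).  The final
    ``len(signal_tokens)`` dimensions form a signal block: dimension *m* is
    ``signal_scale`` for the *m*-th signal token and 0 otherwise, so that
    token-level signals planted by the synthetic data generator remain
    linearly decodable after mean pooling.

    Proteins are tokenized as overlapping 3-mers (recorded in
    :attr:`metadata`), so 3-mer motif content is directly visible at the
    token level; SMILES strings use the standard token regex.  No special
    begin/end tokens are added.
    """

    protein_kmer = 3

    def __init__(
        self,
        spec: EmbeddingSpec | None = None,
        signal_tokens: Mapping[str, Sequence[str]] | None = None,
        signal_scale: float = 4.0,
        seed: int = 0,
    ):
        self.spec = spec or EmbeddingSpec(d_p=64, d_s=32)
        self.signal_tokens = {
            PROTEIN: tuple((signal_tokens or {}).get(PROTEIN, ())),
            MOLECULE: tuple((signal_tokens or {}).get(MOLECULE, ())),
        }
        for mod in MODALITIES:
            if len(self.signal_tokens[mod]) >= self.spec.width(mod):
                raise ValueError(f"too many signal tokens for {mod} width")
        self.signal_scale = float(signal_scale)
        self.seed = int(seed)
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    @property
    def name(self) -> str:
        return f"synthetic-v1(seed={self.seed},kmer={self.protein_kmer})"

    @property
    def metadata(self) -> dict:
        return {
            "name": self.name,
            "protein_tokenization": f"overlapping {self.protein_kmer}-mers",
            "special_tokens": "none",
            "signal_tokens": {k: list(v) for k, v in self.signal_tokens.items()},
            "signal_scale": self.signal_scale,
        }

    def tokenize(self, text: str, modality: str) -> list[str]:
        if modality == MOLECULE:
            return tokenize_smiles(text, self.spec)
        if modality == PROTEIN:
            if not text:
                raise TokenizationError("empty protein sequence")
            seq = text[: self.spec.max_protein_tokens]
            k = self.protein_kmer
            if len(seq) < k:
                return [seq]
            return [seq[i : i + k] for i in range(len(seq) - k + 1)]
        raise EmbeddingError(f"unknown modality {modality!r}")

    def _token_vector(self, token: str, modality: str) -> np.ndarray:
        key = (modality, token)
        vec = self._cache.get(key)
        if vec is None:
            width = self.spec.width(modality)
            n_sig = len(self.signal_tokens[modality])
            rng = np.random.default_rng(_hash_seed(modality, token, self.seed))
            vec = np.zeros(width, dtype=np.float64)
            vec[: width - n_sig] = rng.standard_normal(width - n_sig)
            if token in self.signal_tokens[modality]:
                vec[width - n_sig + self.signal_tokens[modality].index(token)] = self.signal_scale
            self._cache[key] = vec
        return vec

    def embed(self, tokens: Sequence[str], modality: str) -> TokenEmbeddingMatrix:
        if modality not in MODALITIES:
            raise EmbeddingError(f"unknown modality {modality!r}")
        tokens = tuple(tokens[: self.spec.max_tokens(modality)])
        if not tokens:
            raise EmbeddingError("cannot embed an empty token list")
        mat = np.stack([self._token_vector(t, modality) for t in tokens])
        return TokenEmbeddingMatrix(tokens=tokens, matrix=mat)

    def embed_text(self, text: str, modality: str) -> TokenEmbeddingMatrix:
        return self.embed(self.tokenize(text, modality), modality)


def chunk_keys(keys: Sequence[str], chunk_size: int) -> list[list[str]]:
    """Partition keys into consecutive chunks of at most ``chunk_size``."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    return [list(keys[i : i + chunk_size]) for i in range(0, len(keys), chunk_size)]


class EmbeddingStore:
    """Single-file chunked store for per-token embedding matrices.

    Layout: ``/<modality>/chunk_<i>/m<j>`` datasets, each carrying its
    record key as an attribute.  Matrices round-trip bit-exactly; iteration
    loads one chunk at a time.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._f = h5py.File(self.path, mode)
        self._index: dict[str, dict[str, str]] = {}  # modality -> key -> dataset path
        self._build_index()

    def _build_index(self) -> None:
        for modality in self._f:
            idx: dict[str, str] = {}
            for chunk_name in sorted(self._f[modality]):
                grp = self._f[modality][chunk_name]
                for ds_name in grp:
                    idx[grp[ds_name].attrs["key"]] = f"{modality}/{chunk_name}/{ds_name}"
            self._index[modality] = idx

    @classmethod
    def create(cls, path: str | Path) -> "EmbeddingStore":
        return cls(path, mode="w")

    def close(self) -> None:
        self._f.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def write_matrices(
        self,
        modality: str,
        matrices: Mapping[str, TokenEmbeddingMatrix],
        chunk_size: int = 1000,
    ) -> None:
        if modality not in MODALITIES:
            raise EmbeddingError(f"unknown modality {modality!r}")
        keys = list(matrices)
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate keys")
        idx = self._index.setdefault(modality, {})
        dup = [k for k in keys if k in idx]
        if dup:
            raise ValueError(f"keys already stored: {dup[:3]}")
        grp = self._f.require_group(modality)
        start_chunk = len(grp)
        for ci, chunk in enumerate(chunk_keys(keys, chunk_size), start=start_chunk):
            cgrp = grp.create_group(f"chunk_{ci:05d}")
            for j, key in enumerate(chunk):
                ds = cgrp.create_dataset(f"m{j:05d}", data=matrices[key].matrix)
                ds.attrs["key"] = key
                ds.attrs["tokens"] = "\x1f".join(matrices[key].tokens)
                idx[key] = f"{modality}/chunk_{ci:05d}/m{j:05d}"

    def keys(self, modality: str) -> list[str]:
        return list(self._index.get(modality, {}))

    def chunk_names(self, modality: str) -> list[str]:
        if modality not in self._f:
            return []
        return sorted(self._f[modality])

    def get(self, modality: str, key: str) -> TokenEmbeddingMatrix:
        try:
            path = self._index[modality][key]
        except KeyError:
            raise KeyError(f"no stored {modality} embedding for key {key!r}") from None
        ds = self._f[path]
        tokens = tuple(ds.attrs["tokens"].split("\x1f"))
        return TokenEmbeddingMatrix(tokens=tokens, matrix=ds[()])

    def chunk_of(self, modality: str, key: str) -> str:
        try:
            return self._index[modality][key].split("/")[1]
        except KeyError:
            raise KeyError(f"no stored {modality} embedding for key {key!r}") from None

    def iter_chunks(self, modality: str) -> Iterator[dict[str, TokenEmbeddingMatrix]]:
        """Yield one chunk at a time as ``{key: matrix}`` (bounded memory)."""
        if modality not in self._f:
            return
        for chunk_name in sorted(self._f[modality]):
            cgrp = self._f[modality][chunk_name]
            out = {}
            for ds_name in cgrp:
                ds = cgrp[ds_name]
                out[ds.attrs["key"]] = TokenEmbeddingMatrix(
                    tokens=tuple(ds.attrs["tokens"].split("\x1f")), matrix=ds[()]
                )
            yield out

    def load_chunk(self, modality: str, chunk_name: str) -> dict[str, TokenEmbeddingMatrix]:
        cgrp = self._f[modality][chunk_name]
        return {
            cgrp[ds].attrs["key"]: TokenEmbeddingMatrix(
                tokens=tuple(cgrp[ds].attrs["tokens"].split("\x1f")), matrix=cgrp[ds][()]
            )
            for ds in cgrp
        }


def build_store(
    path: str | Path,
    provider: EmbeddingProvider,
    proteins: Mapping[str, str],
    molecules: Mapping[str, str],
    chunk_size: int = 1000,
) -> EmbeddingStore:
    """Embed every unique protein/molecule and persist the matrices."""
    store = EmbeddingStore.create(path)
    prot = {k: provider.embed(provider.tokenize(s, PROTEIN), PROTEIN) for k, s in proteins.items()}
    store.write_matrices(PROTEIN, prot, chunk_size)
    mol = {k: provider.embed(provider.tokenize(s, MOLECULE), MOLECULE) for k, s in molecules.items()}
    store.write_matrices(MOLECULE, mol, chunk_size)
    return store
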