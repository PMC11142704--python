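"""Molecular fingerprints, Jaccard similarity and protein sequence identity.

Used to stratify test-set performance by how close a test molecule or protein
is to the training set: extended-connectivity fingerprints (radius 2, 1024
bits) with Jaccard similarity for molecules, global pairwise alignment for
protein sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

N_FP_BITS = 1024

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_FP_BITS)


class SmilesParseError(ValueError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """1024-bit binary structural fingerprint of one molecule."""

    bits: tuple[int, ...]  # sorted indices of set bits
    source_smiles: str

    def as_array(self) -> np.ndarray:
        v = np.zeros(N_FP_BITS, dtype=np.uint8)
        v[list(self.bits)] = 1
        return v

    def __len__(self) -> int:
        return N_FP_BITS


def ecfp_fingerprint(smiles: str) -> Fingerprint:
    """Radius-2 circular fingerprint hashed to 1024 bits."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    bv = _morgan.GetFingerprint(mol)
    return Fingerprint(bits=tuple(sorted(bv.GetOnBits())), source_smiles=smiles)


def jaccard_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """1 - Jaccard distance = |intersection| / |union| over set bits."""
    sa, sb = set(a.bits), set(b.bits)
    union = sa | sb
    if not union:
        raise ValueError("Jaccard similarity undefined for two all-zero fingerprints")
    return len(sa & sb) / len(union)


def max_similarity_to_set(query: Fingerprint, reference: Sequence[Fingerprint]) -> float:
    """Maximum Jaccard similarity of ``query`` to any reference fingerprint."""
    if not reference:
        raise ValueError("empty reference set")
    return max(jaccard_similarity(query, ref) for ref in reference)


def similarity_matrix(queries: Sequence[Fingerprint], refs: Sequence[Fingerprint]) -> np.ndarray:
    """Pairwise Jaccard similarity, rows = queries, columns = references."""
    out = np.empty((len(queries), len(refs)))
    for i, q in enumerate(queries):
        for j, r in enumerate(refs):
            out[i, j] = jaccard_similarity(q, r)
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_aligner = _make_aligner()


def sequence_identity(a: str, b: str) -> float:
    """Percent identity of two amino-acid sequences under global alignment.

    Identity = matches / alignment length * 100, where the alignment length
    includes gap columns.  Scoring: match +1, mismatch 0, gap -1 (open and
    extend).  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    matches = counts.identities
    length = aln.length
    return 100.0 * matches / length


def max_identity_to_set(query: str, reference: Iterable[str]) -> float:
    """Maximum percent identity of ``query`` against a set of sequences."""
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference set")
    return max(sequence_identity(query, ref) for ref in reference)
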