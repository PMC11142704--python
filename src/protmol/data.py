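"""Interaction records, tabular/FASTA I/O and affinity label transforms.

The central container is :class:`InteractionDataset`, an ordered collection of
(protein, small molecule, label) triples.  Labels carry explicit semantics
(``label_kind``): dissociation constants are handled on the pKd scale,
pKd = -log10(Kd / 1e9) with Kd in nM, so that e.g. Kd = 1 nM maps to pKd = 9.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

LABEL_KINDS = ("pkd", "kd_nm", "ic50", "binary", "log_km", "raw")
TASKS = ("regression", "binary_classification")


class SchemaError(ValueError):
    """A required column is missing or the table layout is invalid."""


class RowValidationError(ValueError):
    """A data row violates a record invariant; carries the row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class InteractionRecord:
    """One protein-molecule interaction measurement."""

    protein_id: str
    sequence: str
    smiles: str
    label: float
    label_kind: str = "raw"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty protein sequence")
        if not self.smiles:
            raise ValueError("empty SMILES string")
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"unknown label_kind {self.label_kind!r}")
        if self.label_kind == "binary" and self.label not in (0.0, 1.0):
            raise ValueError(f"binary label must be 0 or 1, got {self.label}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_id, self.smiles)


@dataclass
class InteractionDataset:
    """Ordered interaction records sharing one label kind and task."""

    records: list[InteractionRecord]
    task: str = "regression"

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        kinds = {r.label_kind for r in self.records}
        if len(kinds) > 1:
            raise ValueError(f"mixed label kinds in dataset: {sorted(kinds)}")
        if self.task == "binary_classification" and kinds and kinds != {"binary"}:
            raise ValueError("binary_classification requires binary labels")
        keys = [r.key for r in self.records]
        n_dup = len(keys) - len(set(keys))
        if n_dup:
            warnings.warn(
                f"{n_dup} duplicate (protein, molecule) pairs kept as replicates",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> InteractionRecord:
        return self.records[i]

    @property
    def labels(self) -> list[float]:
        return [r.label for r in self.records]

    @property
    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def subset(self, indices: Iterable[int]) -> "InteractionDataset":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return InteractionDataset([self.records[i] for i in indices], task=self.task)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
                "label_kind": [r.label_kind for r in self.records],
            }
        )

    def write_table(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "sequence": "sequence",
    "smiles": "smiles",
    "label": "label",
}


def read_interaction_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    task: str = "regression",
    label_kind: str | None = None,
    sep: str = "\t",
    fasta: str | Path | None = None,
) -> InteractionDataset:
    """Read a delimited interaction table into an :class:`InteractionDataset`.

    Parameters
    ----------
    column_map
        Maps the canonical field names (``protein_id``, ``sequence``,
        ``smiles``, ``label``) to the column names in the file.  ``sequence``
        may be omitted when ``fasta`` is given.
    fasta
        Optional FASTA file supplying sequences, joined on ``protein_id``.
    label_kind
        Semantics of the label column; defaults to ``binary`` for
        classification tasks and ``raw`` otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep)

    seq_from_fasta = fasta is not None
    needed = ["protein_id", "smiles", "label"] + ([] if seq_from_fasta else ["sequence"])
    for canon in needed:
        if cols[canon] not in df.columns:
            raise SchemaError(
                f"missing column {cols[canon]!r} (for field {canon!r}) in {path.name}"
            )

    seq_by_id: dict[str, str] = {}
    if seq_from_fasta:
        seq_by_id = read_fasta_sequences(fasta)

    if label_kind is None:
        label_kind = "binary" if task == "binary_classification" else "raw"

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        pid = str(row[cols["protein_id"]])
        if seq_from_fasta:
            seq = seq_by_id.get(pid, "")
            if not seq:
                raise RowValidationError(f"protein_id {pid!r} not found in FASTA", i)
        else:
            seq = "" if pd.isna(row[cols["sequence"]]) else str(row[cols["sequence"]])
        smi = row[cols["smiles"]]
        smi = "" if pd.isna(smi) else str(smi)
        try:
            records.append(
                InteractionRecord(
                    protein_id=pid,
                    sequence=seq,
                    smiles=smi,
                    label=float(row[cols["label"]]),
                    label_kind=label_kind,
                )
            )
        except ValueError as e:
            raise RowValidationError(str(e), i) from e
    return InteractionDataset(records, task=task)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_predictions(
    data: InteractionDataset,
    predictions: Sequence[float],
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write record keys plus model predictions as a delimited table."""
    if len(predictions) != len(data):
        raise ValueError(f"{len(predictions)} predictions for {len(data)} records")
    df = pd.DataFrame(
        {
            "protein_id": data.protein_ids,
            "smiles": data.smiles,
            "label": data.labels,
            "prediction": list(predictions),
        }
    )
    df.to_csv(path, sep=sep, index=False)


def transform_affinity(value: float, from_kind: str, to_kind: str) -> float:
    """Convert an affinity label between scales.

    Supported: ``kd_nm`` <-> ``pkd`` with pKd = -log10(Kd / 1e9), Kd in nM.
    Identity for equal kinds.
    """
    if from_kind == to_kind:
        return float(value)
    if (from_kind, to_kind) == ("kd_nm", "pkd"):
        if value <= 0:
            raise ValueError(f"Kd must be positive for the log transform, got {value}")
        return -math.log10(value / 1e9)
    if (from_kind, to_kind) == ("pkd", "kd_nm"):
        return 10.0 ** (-value) * 1e9
    raise ValueError(f"unsupported transform {from_kind!r} -> {to_kind!r}")


def with_transformed_labels(
    data: InteractionDataset, to_kind: str
) -> InteractionDataset:
    """Return a copy of the dataset with labels converted to ``to_kind``."""
    recs = [
        replace(r, label=transform_affinity(r.label, r.label_kind, to_kind), label_kind=to_kind)
        for r in data.records
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return InteractionDataset(recs, task=data.task)
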