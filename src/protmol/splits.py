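"""Train/validation/test split construction and stratified evaluation.

Scenarios follow the standard drug-target benchmarking protocol: a random
80/10/10 record split; *cold target* (no test/validation protein appears in
training); *cold drug* (no test/validation molecule appears in training);
*cold both*; and a pair-exclusion split where the same (protein, molecule)
pair never straddles train and test.  Cold splits partition entities first
and then assign records, so record-level fractions approximate 80/10/10 as
closely as the entity partition allows.  Each scenario supports repeated
independent splits (default 5).

Occurrence-frequency-controlled splits fix, for a set of randomly selected
test drugs, exactly k training pairs with that drug (k in {1, 3, 10, 30,
100}), to probe how performance depends on how often a drug was seen.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .data import InteractionDataset

SCENARIOS = ("random", "cold_target", "cold_drug", "cold_both", "same_pair_excluded")


class FeasibilityError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    scenario: str = "random"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SplitResult:
    train: list[int]
    val: list[int]
    test: list[int]
    manifest: dict = field(default_factory=dict)

    @property
    def parts(self) -> dict[str, list[int]]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record_index": i, "part": part}
            for part, idxs in self.parts.items()
            for i in idxs
        ]
        df = pd.DataFrame(rows)
        for k, v in self.manifest.items():
            if isinstance(v, (str, int, float)):
                df[k] = v
        return df


def _split_indices_random(n: int, fractions, rng) -> tuple[list[int], list[int], list[int]]:
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return (
        sorted(order[:n_train].tolist()),
        sorted(order[n_train : n_train + n_val].tolist()),
        sorted(order[n_train + n_val :].tolist()),
    )


def _entity_partition(
    entities: Sequence[str],
    counts: Mapping[str, int],
    fractions,
    rng,
) -> dict[str, int]:
    """Assign entities to parts 0/1/2 greedily so record counts track fractions."""
    if len(entities) < 3:
        raise FeasibilityError(
            f"need at least 3 entities to populate train/val/test, got {len(entities)}"
        )
    total = sum(counts.values())
    targets = [fractions[0] * total, (fractions[0] + fractions[1]) * total]
    order = rng.permutation(len(entities))
    assign: dict[str, int] = {}
    cum = 0
    for idx in order:
        e = entities[idx]
        if cum < targets[0]:
            assign[e] = 0
        elif cum < targets[1]:
            assign[e] = 1
        else:
            assign[e] = 2
        cum += counts[e]
    # with few entities the greedy walk can skip a band entirely; repopulate
    # empty parts from the largest part (smallest donors first)
    for part in (1, 2):
        if part not in assign.values():
            donors = [e for e, p in assign.items() if p == 0]
            if len(donors) < 2:
                donors = [e for e, p in assign.items() if p != part]
            donor = min(donors, key=lambda e: counts[e])
            assign[donor] = part
    return assign


def _one_split(data: InteractionDataset, spec: SplitSpec, rng) -> SplitResult:
    n = len(data)
    scenario = spec.scenario
    manifest: dict = {"scenario": scenario}

    if scenario == "random":
        tr, va, te = _split_indices_random(n, spec.fractions, rng)
    elif scenario in ("cold_target", "cold_drug", "cold_both"):
        prot = data.protein_ids
        mol = data.smiles
        uniq_p = sorted(set(prot))
        uniq_m = sorted(set(mol))
        if len(uniq_p) < 2 or len(uniq_m) < 2:
            raise FeasibilityError(
                f"cold scenarios need >= 2 proteins and >= 2 molecules "
                f"(got {len(uniq_p)}, {len(uniq_m)})"
            )
        p_counts = defaultdict(int)
        m_counts = defaultdict(int)
        for p, m in zip(prot, mol):
            p_counts[p] += 1
            m_counts[m] += 1
        parts: list[list[int]] = [[], [], []]
        discarded: list[int] = []
        if scenario == "cold_target":
            assign = _entity_partition(uniq_p, p_counts, spec.fractions, rng)
            for i, p in enumerate(prot):
                parts[assign[p]].append(i)
        elif scenario == "cold_drug":
            assign = _entity_partition(uniq_m, m_counts, spec.fractions, rng)
            for i, m in enumerate(mol):
                parts[assign[m]].append(i)
        else:  # cold_both: record kept only when both entities share a part
            p_assign = _entity_partition(uniq_p, p_counts, spec.fractions, rng)
            m_assign = _entity_partition(uniq_m, m_counts, spec.fractions, rng)
            for i, (p, m) in enumerate(zip(prot, mol)):
                if p_assign[p] == m_assign[m]:
                    parts[p_assign[p]].append(i)
                else:
                    discarded.append(i)
            manifest["n_discarded_cross_pairs"] = len(discarded)
        tr, va, te = parts
        if not va or not te:
            raise FeasibilityError(f"{scenario}: empty validation or test part")
    elif scenario == "same_pair_excluded":
        keys = sorted({r.key for r in data})
        by_key = defaultdict(list)
        for i, r in enumerate(data):
            by_key[r.key].append(i)
        counts = {k: len(by_key[k]) for k in keys}
        assign = _entity_partition(keys, counts, spec.fractions, rng)
        parts = [[], [], []]
        for k in keys:
            parts[assign[k]].extend(by_key[k])
        tr, va, te = (sorted(p) for p in parts)
    else:  # pragma: no cover
        raise ValueError(scenario)

    manifest["overlap"] = audit_overlaps(data, tr, va, te)
    return SplitResult(train=list(tr), val=list(va), test=list(te), manifest=manifest)


def audit_overlaps(data, train, val, test) -> dict[str, int]:
    """Entity overlap counts between train and the held-out parts."""
    tp = {data[i].protein_id for i in train}
    tm = {data[i].smiles for i in train}
    held = list(val) + list(test)
    return {
        "protein_overlap": len(tp & {data[i].protein_id for i in held}),
        "molecule_overlap": len(tm & {data[i].smiles for i in held}),
    }


def make_split(data: InteractionDataset, spec: SplitSpec) -> list[SplitResult]:
    """Generate ``spec.n_repeats`` independent splits, reproducible per seed."""
    results = []
    for rep in range(spec.n_repeats):
        rng = np.random.default_rng([spec.seed, rep])
        res = _one_split(data, spec, rng)
        res.manifest.update({"repeat": rep, "seed": spec.seed})
        results.append(res)
    return results


def occurrence_controlled_split(
    data: InteractionDataset,
    k: int,
    n_test_drugs: int = 15,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitResult:
    """Fix the training occurrence count of selected test drugs to exactly k.

    For each of ``n_test_drugs`` randomly selected eligible molecules
    (those with more than k records), exactly k of its records (all with
    distinct proteins) go to training and the rest to test.  Records of all
    other molecules are split randomly.
    """
    rng = np.random.default_rng([seed, k])
    by_mol: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(data):
        by_mol[r.smiles].append(i)

    def n_distinct_prot(idxs):
        return len({data[i].protein_id for i in idxs})

    eligible = [m for m, idxs in by_mol.items() if len(idxs) > k and n_distinct_prot(idxs) >= k + 1]
    if len(eligible) < n_test_drugs:
        raise FeasibilityError(
            f"only {len(eligible)} molecules have more than k={k} records with "
            f"distinct proteins; need {n_test_drugs}"
        )
    selected = [eligible[i] for i in rng.choice(len(eligible), n_test_drugs, replace=False)]

    train: list[int] = []
    test: list[int] = []
    for m in selected:
        idxs = list(by_mol[m])
        rng.shuffle(idxs)
        chosen: list[int] = []
        seen_prot: set[str] = set()
        for i in idxs:
            if data[i].protein_id not in seen_prot and len(chosen) < k:
                chosen.append(i)
                seen_prot.add(data[i].protein_id)
        train.extend(chosen)
        test.extend(i for i in idxs if i not in chosen)

    rest = [i for m, idxs in by_mol.items() if m not in selected for i in idxs]
    rest_order = rng.permutation(len(rest))
    n_tr = int(round(fractions[0] * len(rest)))
    n_va = int(round(fractions[1] * len(rest)))
    val: list[int] = []
    for j, oi in enumerate(rest_order):
        i = rest[oi]
        if j < n_tr:
            train.append(i)
        elif j < n_tr + n_va:
            val.append(i)
        else:
            test.append(i)
    manifest = {
        "scenario": "occurrence_controlled",
        "k": k,
        "seed": seed,
        "selected_molecules": selected,
    }
    return SplitResult(train=sorted(train), val=sorted(val), test=sorted(test), manifest=manifest)


_METRIC_FNS: dict[str, Callable] = {
    "mse": lambda y, p: _metrics.regression_metrics(y, p)["mse"],
    "r_squared": lambda y, p: _metrics.regression_metrics(y, p)["r_squared"],
    "pearson_r": lambda y, p: _metrics.regression_metrics(y, p)["pearson_r"],
    "concordance_index": _metrics.concordance_index,
    "rm_squared": lambda y, p: _metrics.rm_squared(y, p)["rm_squared"],
    "accuracy": lambda y, p: _metrics.binary_metrics(y, p)["accuracy"],
    "mcc": lambda y, p: _metrics.binary_metrics(y, p)["mcc"],
    "roc_auc": lambda y, p: _metrics.binary_metrics(y, p)["roc_auc"],
}


def stratified_metrics(
    y: Sequence[float],
    yhat: Sequence[float],
    key_values: Sequence[float],
    bin_edges: Sequence[float],
    metric: str,
) -> pd.DataFrame:
    """Metric per key-value bin; bins are left-closed, right-open.

    Every key value must fall into some ``[edge_i, edge_{i+1})`` interval so
    that bin counts sum to the number of records.  Empty bins are reported
    with count 0 and a missing metric value; a bin where the metric is
    undefined (e.g. single-class labels) is reported with its count and a
    missing value.
    """
    if metric not in _METRIC_FNS:
        raise KeyError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FNS)}")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    kv = np.asarray(key_values, dtype=float)
    if not (len(y) == len(yhat) == len(kv)):
        raise ValueError("y, yhat and key_values must have equal length")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not (np.diff(edges) > 0).all():
        raise ValueError("bin_edges must be increasing with at least two edges")
    if ((kv < edges[0]) | (kv >= edges[-1])).any():
        raise ValueError("key values outside [first_edge, last_edge) range")
    which = np.digitize(kv, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        count = int(sel.sum())
        value = None
        if count > 0:
            try:
                value = float(_METRIC_FNS[metric](y[sel], yhat[sel]))
            except (ValueError, _metrics.MetricUndefinedError) as e:
                warnings.warn(f"bin [{edges[b]}, {edges[b+1]}): {e}", stacklevel=2)
        rows.append(
            {"bin_left": edges[b], "bin_right": edges[b + 1], "count": count, metric: value}
        )
    return pd.DataFrame(rows)
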