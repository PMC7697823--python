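"""Aggregation of attention maps into heat-map and ranking payloads.

Turns per-sample attention into the exports a visual front end consumes:
a mean heat map over a patient group, an individual map, their difference
(individual minus group, which may be negative), a threshold filter over
entries, and a top-k variable ranking optionally nested by vocabulary
category (a treemap payload).  Days run along one axis and variables along
the other; masked (padded) days contribute zero weight, so when group
members have unequal stay lengths the later rows of a mean map sum to less
than one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ShapeError
from .model import AttentionMap

Kind = str  # one of {"mean", "individual", "difference"}


@dataclass
class HeatmapPayload:
    """[T x F] matrix with day/variable labels and an aggregation kind."""

    matrix: np.ndarray  # [T, F]
    days: list[int]
    variables: list[str]
    kind: Kind

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "days": self.days,
            "variables": self.variables,
            "matrix": [[float(v) for v in row] for row in self.matrix],
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "HeatmapPayload":
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            days=list(d["days"]),
            variables=list(d["variables"]),
            kind=d["kind"],
        )


def _variable_labels(maps: AttentionMap, vocabulary: pd.DataFrame | None) -> list[str]:
    labels = {}
    if vocabulary is not None:
        labels = {int(r.event_id): str(r.label) for r in vocabulary.itertuples(index=False)}
    cols = sorted(maps.feature_index.items(), key=lambda kv: kv[1])
    return [labels.get(eid, str(eid)) for eid, _ in cols]


def _select(maps: AttentionMap, subset: set[int] | None) -> np.ndarray:
    if subset is None:
        return np.arange(maps.weights.shape[0])
    keys = maps.sample_keys or list(range(maps.weights.shape[0]))
    bad = subset - set(keys)
    if bad:
        raise ArgumentError(f"subset keys not in attention maps: {sorted(bad)}")
    return np.array([i for i, k in enumerate(keys) if k in subset], dtype=int)


def mean_attention(
    maps: AttentionMap,
    subset: set[int] | None = None,
    vocabulary: pd.DataFrame | None = None,
) -> HeatmapPayload:
    """Entrywise mean attention over the selected samples (kind='mean')."""
    if maps.weights.shape[0] == 0:
        raise ArgumentError("attention maps are empty")
    idx = _select(maps, subset)
    if idx.size == 0:
        raise ArgumentError("subset selects no samples")
    matrix = maps.weights[idx].mean(axis=0)
    return HeatmapPayload(
        matrix=matrix,
        days=list(range(matrix.shape[0])),
        variables=_variable_labels(maps, vocabulary),
        kind="mean",
    )


def individual_attention(
    maps: AttentionMap,
    key: int,
    vocabulary: pd.DataFrame | None = None,
) -> HeatmapPayload:
    """A single sample's attention map (kind='individual')."""
    payload = mean_attention(maps, subset={key}, vocabulary=vocabulary)
    payload.kind = "individual"
    return payload


def sample_attention(maps: AttentionMap, fraction: float, seed: int = 0) -> AttentionMap:
    """Seeded uniform subsample of samples (e.g. 15% before aggregation)."""
    if not 0 < fraction <= 1:
        raise ArgumentError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = maps.weights.shape[0]
    k = max(1, int(round(fraction * n)))
    idx = np.sort(rng.choice(n, size=k, replace=False))
    keys = maps.sample_keys or list(range(n))
    return AttentionMap(
        weights=maps.weights[idx],
        mask=maps.mask[idx],
        feature_index=maps.feature_index,
        sample_keys=[keys[i] for i in idx],
    )


def attention_difference(group: HeatmapPayload, individual: HeatmapPayload) -> HeatmapPayload:
    """Entrywise (individual - group); entries may be negative."""
    if group.matrix.shape != individual.matrix.shape:
        raise ShapeError(
            f"shape mismatch: group {group.matrix.shape} vs individual {individual.matrix.shape}"
        )
    return HeatmapPayload(
        matrix=individual.matrix - group.matrix,
        days=list(group.days),
        variables=list(group.variables),
        kind="difference",
    )


def threshold_filter(
    payload: HeatmapPayload, threshold: float
) -> list[tuple[int, str, float]]:
    """(day, variable, value) triples with value >= threshold, sorted
    descending by value (ties broken by day then variable)."""
    T, F = payload.matrix.shape
    entries = [
        (payload.days[t], payload.variables[f], float(payload.matrix[t, f]))
        for t in range(T)
        for f in range(F)
        if payload.matrix[t, f] >= threshold
    ]
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return entries


def top_k_variables(
    payload: HeatmapPayload,
    k: int,
    group_by_category: bool = False,
    vocabulary: pd.DataFrame | None = None,
    aggregate: str = "sum",
) -> list[tuple[str, float]] | dict:
    """Variables ranked by attention aggregated over days.

    ``aggregate`` is ``"sum"`` (default) or ``"mean"`` over days.  Ties
    break by variable label.  With ``group_by_category`` the ranked events
    nest under their vocabulary category with category totals (a treemap
    payload); otherwise a ranked ``(label, value)`` list is returned.
    Requesting more than F variables returns all F with a warning.
    """
    if k < 1:
        raise ArgumentError("k must be >= 1")
    if aggregate not in ("sum", "mean"):
        raise ArgumentError("aggregate must be 'sum' or 'mean'")
    agg = payload.matrix.sum(axis=0) if aggregate == "sum" else payload.matrix.mean(axis=0)
    order = sorted(
        range(len(payload.variables)),
        key=lambda f: (-agg[f], payload.variables[f]),
    )
    if k > len(order):
        import logging

        logging.getLogger(__name__).warning(
            "top_k_variables: k=%d exceeds %d variables; returning all", k, len(order)
        )
        k = len(order)
    ranked = [(payload.variables[f], float(agg[f])) for f in order[:k]]
    if not group_by_category:
        return ranked
    cats = {}
    if vocabulary is not None:
        cats = {str(r.label): str(r.category) for r in vocabulary.itertuples(index=False)}
    grouped: dict[str, list[tuple[str, float]]] = {}
    for label, value in ranked:
        grouped.setdefault(cats.get(label, "unknown"), []).append((label, value))
    categories = [
        {
            "name": name,
            "total": float(sum(v for _, v in events)),
            "events": [{"label": lab, "value": val} for lab, val in events],
        }
        for name, events in grouped.items()
    ]
    categories.sort(key=lambda c: (-c["total"], c["name"]))
    return {"categories": categories}


def write_topk(payload: dict | list, path: str | Path) -> None:
    if isinstance(payload, list):
        payload = {"ranking": [{"label": lab, "value": val} for lab, val in payload]}
    Path(path).write_text(json.dumps(payload, indent=1))
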