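"""Pathway graphs and cohort selection by pathway.

Mined patterns are merged into a staged flow graph (the payload behind a
Sankey / flowchart view of clinical pathways): nodes are keyed by
(stage, event label) so an event recurring at two positions yields two
nodes, node weights sum the supports of the patterns passing through, and
links connect consecutive stages.  A chosen pathway then selects a cohort:
every sequence containing the pathway as an order-preserving, gap-allowed
subsequence is matched and labeled 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ArgumentError
from .mining import Pattern, pattern_support
from .sequences import SequenceDatabase


@dataclass(frozen=True)
class PathwayNode:
    stage: int
    label: str
    weight: int


@dataclass(frozen=True)
class PathwayLink:
    source: int  # node index
    target: int
    weight: int


@dataclass
class PathwayGraph:
    nodes: list[PathwayNode]
    links: list[PathwayLink]

    def node_index(self) -> dict[tuple[int, str], int]:
        return {(n.stage, n.label): i for i, n in enumerate(self.nodes)}


def _element_label(element: tuple[int, ...], db: SequenceDatabase | None) -> str:
    labs = [db.label_of(e) if db else str(e) for e in element]
    return labs[0] if len(labs) == 1 else "{" + "+".join(labs) + "}"


def merge_patterns(
    patterns: Sequence[Pattern], db: SequenceDatabase | None = None
) -> PathwayGraph:
    """Merge patterns into a staged pathway graph.

    Node (stage s, label L) accumulates the support of every pattern whose
    element at position s bears label L; a link (s, L) -> (s+1, M)
    accumulates the support of patterns with that consecutive label pair.
    Ordering of nodes and links is deterministic (by stage, then label).
    """
    if not patterns:
        raise ArgumentError("patterns must be nonempty")
    node_w: dict[tuple[int, str], int] = {}
    link_w: dict[tuple[int, str, str], int] = {}
    for p in patterns:
        labels = [_element_label(el, db) for el in p.elements]
        for s, lab in enumerate(labels):
            node_w[(s, lab)] = node_w.get((s, lab), 0) + p.support_count
        for s in range(len(labels) - 1):
            key = (s, labels[s], labels[s + 1])
            link_w[key] = link_w.get(key, 0) + p.support_count
    nodes = [
        PathwayNode(stage=s, label=lab, weight=w)
        for (s, lab), w in sorted(node_w.items())
    ]
    index = {(n.stage, n.label): i for i, n in enumerate(nodes)}
    links = [
        PathwayLink(source=index[(s, a)], target=index[(s + 1, b)], weight=w)
        for (s, a, b), w in sorted(link_w.items())
    ]
    return PathwayGraph(nodes=nodes, links=links)


@dataclass
class CohortSelection:
    """Binary cohort labeling induced by one pathway over a database."""

    pathway: list[int]
    matched_keys: set[int]
    labels: dict[int, int]

    @property
    def size(self) -> int:
        return len(self.matched_keys)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"key": list(self.labels), "label": list(self.labels.values())}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def resolve_pathway(
    db: SequenceDatabase, pathway: Sequence[int | str]
) -> list[int]:
    """Map a pathway given as event ids and/or labels to event ids."""
    resolved: list[int] = []
    unknown: list[str] = []
    for ev in pathway:
        if isinstance(ev, str):
            eid = db.id_of_label(ev)
            if eid is None:
                try:
                    eid = int(ev)
                except ValueError:
                    eid = None
            if eid is None or eid not in db.vocabulary:
                unknown.append(ev)
                continue
            resolved.append(eid)
        else:
            if int(ev) not in db.vocabulary:
                unknown.append(str(ev))
                continue
            resolved.append(int(ev))
    if unknown:
        raise ArgumentError(f"unknown pathway events: {unknown}")
    return resolved


def match_pathway(
    db: SequenceDatabase, pathway: Sequence[int | str]
) -> CohortSelection:
    """Select the cohort of sequences containing ``pathway``.

    Each pathway event is treated as a singleton element; containment is
    order-preserving and gap-allowed.  The empty pathway matches every
    sequence.
    """
    ids = resolve_pathway(db, pathway)
    if not ids:
        matched = set(db.keys())
    else:
        pat = [frozenset((e,)) for e in ids]
        matched = set()
        for s in db.sequences:
            i = 0
            for el in s.elements:
                if pat[i].issubset(el):
                    i += 1
                    if i == len(pat):
                        matched.add(s.key)
                        break
    labels = {k: int(k in matched) for k in db.keys()}
    return CohortSelection(pathway=ids, matched_keys=matched, labels=labels)


def export_sankey(graph: PathwayGraph) -> dict:
    """Sankey JSON payload; links reference nodes by id."""
    return {
        "nodes": [
            {"id": i, "stage": n.stage, "label": n.label, "weight": n.weight}
            for i, n in enumerate(graph.nodes)
        ],
        "links": [
            {"source": l.source, "target": l.target, "weight": l.weight}
            for l in graph.links
        ],
    }


def import_sankey(payload: dict) -> PathwayGraph:
    nodes = [
        PathwayNode(stage=n["stage"], label=n["label"], weight=n["weight"])
        for n in sorted(payload["nodes"], key=lambda n: n["id"])
    ]
    links = [
        PathwayLink(source=l["source"], target=l["target"], weight=l["weight"])
        for l in payload["links"]
    ]
    return PathwayGraph(nodes=nodes, links=links)


def write_sankey(graph: PathwayGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(export_sankey(graph), indent=1))


def cohort_size_check(db: SequenceDatabase, pathway: Sequence[int | str]) -> bool:
    """Cross-check: |matched| equals pattern_support on the same pathway."""
    sel = match_pathway(db, pathway)
    if not sel.pathway:
        return sel.size == db.n
    return sel.size == pattern_support(db, [(e,) for e in sel.pathway])
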