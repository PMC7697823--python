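"""Closed sequential pattern mining over a SequenceDatabase.

A *pattern* is an ordered list of elements (itemsets); a database sequence
contains it when the pattern's elements can be matched, in order and with
gaps allowed, to sequence elements of which they are subsets, at strictly
increasing positions.  A frequent pattern is *closed* when no super-pattern
has the same support, so the closed set is a lossless, compact summary of
all frequent sequential patterns — the representation used to surface
clinical pathways from hospitalization event sequences.

The miner grows patterns depth-first in canonical order (append a new
singleton element, or extend the last element with a strictly larger item),
counting support only within the parent pattern's supporting sequences —
anti-monotonicity makes that sound — and closes the result with an
equal-support sub-pattern filter.  ``brute_force_closed_patterns``
re-derives the same set by exhaustive enumeration and is the correctness
oracle for small databases.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ArgumentError, SizeError
from .sequences import SequenceDatabase

Elements = tuple[tuple[int, ...], ...]


@dataclass(frozen=True)
class Pattern:
    """An ordered event pattern with its support in a database."""

    elements: Elements
    support_count: int
    support_rate: float
    closed: bool = True

    def label_text(self, db: SequenceDatabase | None = None) -> str:
        def fmt(el: tuple[int, ...]) -> str:
            labs = [db.label_of(e) if db else str(e) for e in el]
            return labs[0] if len(labs) == 1 else "{" + ",".join(labs) + "}"

        return " ->".join(fmt(el) for el in self.elements)


@dataclass
class MiningResult:
    patterns: list[Pattern]
    min_support_rate: float
    min_support_count: int
    db_size: int
    elapsed: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "db_size": self.db_size,
                "min_support_rate": self.min_support_rate,
                "min_support_count": self.min_support_count,
                "patterns": [
                    {
                        "elements": [list(el) for el in p.elements],
                        "support_count": p.support_count,
                        "support_rate": p.support_rate,
                    }
                    for p in self.patterns
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MiningResult":
        d = json.loads(text)
        pats = [
            Pattern(
                elements=tuple(tuple(int(e) for e in el) for el in p["elements"]),
                support_count=int(p["support_count"]),
                support_rate=float(p["support_rate"]),
            )
            for p in d["patterns"]
        ]
        return cls(
            patterns=pats,
            min_support_rate=float(d["min_support_rate"]),
            min_support_count=int(d["min_support_count"]),
            db_size=int(d["db_size"]),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def to_table(self, db: SequenceDatabase | None = None) -> str:
        """Flat text table: 'No.  Pattern  Support (%)'."""
        lines = ["No.\tPattern\tSupport (%)"]
        for i, p in enumerate(self.patterns, start=1):
            lines.append(f"{i}\t{p.label_text(db)}\t{100 * p.support_rate:.3g}")
        return "\n".join(lines)


def _contains(seq: Sequence[frozenset], pattern: Elements) -> bool:
    """Greedy order-preserving, gap-allowed containment with subset elements."""
    i = 0
    n = len(pattern)
    for el in seq:
        if el.issuperset(pattern[i]):
            i += 1
            if i == n:
                return True
    return False


def _as_sets(db: SequenceDatabase) -> list[list[frozenset]]:
    return [[frozenset(el) for el in s.elements] for s in db.sequences]


def pattern_support(db: SequenceDatabase, elements: Sequence[Sequence[int]]) -> int:
    """Number of database sequences containing ``elements`` as a pattern."""
    pat: Elements = tuple(tuple(el) for el in elements)
    if not pat or any(len(el) == 0 for el in pat):
        raise ArgumentError("pattern must be a nonempty list of nonempty elements")
    pat = tuple(tuple(sorted(set(el))) for el in pat)
    return sum(1 for seq in _as_sets(db) if _contains(seq, pat))


def _sort_key(p: Pattern):
    # descending support, then total items, then lexicographic elements
    return (-p.support_count, sum(len(el) for el in p.elements), p.elements)


def _pattern_contains_pattern(big: Elements, small: Elements) -> bool:
    return _contains([frozenset(el) for el in big], small)


def _closed_filter(frequent: dict[Elements, int]) -> dict[Elements, int]:
    """Drop any pattern with an equal-support super-pattern in ``frequent``.

    Sufficient for closedness: a super-pattern's support never exceeds the
    sub-pattern's, so an equal-support super-pattern of a frequent pattern
    is itself frequent and present in the enumeration.
    """
    by_support: dict[int, list[Elements]] = {}
    for pat, sup in frequent.items():
        by_support.setdefault(sup, []).append(pat)
    closed: dict[Elements, int] = {}
    for sup, group in by_support.items():
        for pat in group:
            n_items = sum(len(el) for el in pat)
            absorbed = any(
                other != pat
                and sum(len(el) for el in other) > n_items
                and _pattern_contains_pattern(other, pat)
                for other in group
            )
            if not absorbed:
                closed[pat] = sup
    return closed


def mine_closed_patterns(
    db: SequenceDatabase,
    min_support_rate: float,
    max_length: int | None = None,
) -> MiningResult:
    """Exact closed frequent sequential patterns at a minimum support rate.

    The absolute threshold is ``ceil(min_support_rate * n)``.  Returns every
    pattern with support at or above the threshold such that no
    super-pattern has equal support, each annotated with its exact support,
    sorted by (descending support, length, lexicographic event ids).

    ``max_length`` optionally caps the number of items per pattern.
    """
    if not 0.0 < min_support_rate <= 1.0:
        raise ArgumentError("min_support_rate must be in (0, 1]")
    if db.n == 0:
        raise ArgumentError("database must be nonempty")
    t0 = time.perf_counter()
    n = db.n
    minsup = math.ceil(min_support_rate * n)
    seqs = _as_sets(db)

    item_support: dict[int, list[int]] = {}
    for idx, seq in enumerate(seqs):
        seen: set[int] = set()
        for el in seq:
            seen.update(el)
        for item in seen:
            item_support.setdefault(item, []).append(idx)
    freq_items = sorted(i for i, ids in item_support.items() if len(ids) >= minsup)

    frequent: dict[Elements, int] = {}

    def supporting(pattern: Elements, candidates: list[int]) -> list[int]:
        return [i for i in candidates if _contains(seqs[i], pattern)]

    def grow(pattern: Elements, support_ids: list[int], n_items: int) -> None:
        frequent[pattern] = len(support_ids)
        if max_length is not None and n_items >= max_length:
            return
        last = pattern[-1]
        for item in freq_items:
            # sequence extension: append a new singleton element
            cand = pattern + ((item,),)
            ids = supporting(cand, support_ids)
            if len(ids) >= minsup:
                grow(cand, ids, n_items + 1)
            # itemset extension: enlarge the last element, canonical order
            if item > last[-1]:
                cand = pattern[:-1] + (last + (item,),)
                ids = supporting(cand, support_ids)
                if len(ids) >= minsup:
                    grow(cand, ids, n_items + 1)

    for item in freq_items:
        ids = item_support[item]
        grow(((item,),), ids, 1)

    closed = _closed_filter(frequent)
    patterns = [
        Pattern(elements=pat, support_count=sup, support_rate=sup / n, closed=True)
        for pat, sup in closed.items()
    ]
    patterns.sort(key=_sort_key)
    return MiningResult(
        patterns=patterns,
        min_support_rate=min_support_rate,
        min_support_count=minsup,
        db_size=n,
        elapsed=time.perf_counter() - t0,
    )


def brute_force_closed_patterns(
    db: SequenceDatabase,
    min_support_rate: float,
    max_total_events: int = 64,
) -> MiningResult:
    """Exhaustive-enumeration oracle for :func:`mine_closed_patterns`.

    Enumerates every sub-pattern of every database sequence (all ordered
    position subsets, all nonempty item subsets per chosen element), counts
    support independently, keeps the frequent ones and removes any pattern
    with an equal-support super-pattern.  Guarded to small databases.
    """
    if not 0.0 < min_support_rate <= 1.0:
        raise ArgumentError("min_support_rate must be in (0, 1]")
    if db.n == 0:
        raise ArgumentError("database must be nonempty")
    total = sum(len(el) for s in db.sequences for el in s.elements)
    if total > max_total_events:
        raise SizeError(
            f"brute-force oracle guard: {total} events exceeds limit {max_total_events}"
        )
    t0 = time.perf_counter()
    n = db.n
    minsup = math.ceil(min_support_rate * n)
    seqs = _as_sets(db)

    def item_subsets(el: frozenset) -> list[tuple[int, ...]]:
        items = sorted(el)
        out: list[tuple[int, ...]] = []
        for mask in range(1, 1 << len(items)):
            out.append(tuple(items[i] for i in range(len(items)) if mask >> i & 1))
        return out

    candidates: set[Elements] = set()
    for seq in seqs:
        partial: list[Elements] = [()]
        for el in seq:
            subs = item_subsets(el)
            new = [p + (s,) for p in partial for s in subs]
            partial.extend(new)
        candidates.update(p for p in partial if p)

    support = {
        pat: sum(1 for seq in seqs if _contains(seq, pat)) for pat in candidates
    }
    frequent = {pat: sup for pat, sup in support.items() if sup >= minsup}
    closed = _closed_filter(frequent)
    patterns = [
        Pattern(elements=pat, support_count=sup, support_rate=sup / n, closed=True)
        for pat, sup in closed.items()
    ]
    patterns.sort(key=_sort_key)
    return MiningResult(
        patterns=patterns,
        min_support_rate=min_support_rate,
        min_support_count=minsup,
        db_size=n,
        elapsed=time.perf_counter() - t0,
    )
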