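"""Record cleaning and sequence-database construction.

Raw EHR extracts arrive as three delimited tables (events, admissions,
vocabulary).  This module cleans the event table against the admission
windows, optionally restricts it to a clinical context, rolls event codes
up a concept hierarchy, buckets timestamps, and finally converts the rows
into a :class:`SequenceDatabase` — ordered element sequences keyed by
patient or admission — ready for sequential pattern mining.

Conventions
-----------
* A record whose ``hadm_id`` is unknown, or whose timestamp falls outside
  ``[admit_time, min(discharge_time, death_time)]``, is treated as an entry
  error and dropped.
* Elements are ordered by (bucketed timestamp, input row order, event_id);
  the default ``element-per-event`` mode emits one singleton element per
  record, while ``itemset-per-bucket`` groups same-bucket records into one
  sorted, de-duplicated itemset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["subject_id", "hadm_id", "timestamp", "event_id", "event_value", "category"]
ADMISSION_COLUMNS = ["hadm_id", "subject_id", "admit_time", "discharge_time", "death_time", "admission_type"]
VOCAB_COLUMNS = ["event_id", "label", "category", "hierarchy_path"]

Unit = Literal["patient", "admission"]
Mode = Literal["element-per-event", "itemset-per-bucket"]
Resolution = Literal["none", "day", "admission"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing required column {col!r}")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["subject_id", "hadm_id", "timestamp", "event_id"], "event")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_admissions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["hadm_id", "subject_id", "admit_time", "discharge_time"], "admission")
    for col in ("admit_time", "discharge_time", "death_time"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def read_vocabulary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["event_id", "label", "category"], "vocabulary")
    if "hierarchy_path" not in df.columns:
        df["hierarchy_path"] = ""
    df["hierarchy_path"] = df["hierarchy_path"].fillna("")
    return df


def vocabulary_index(vocabulary: pd.DataFrame) -> dict[int, tuple[str, str, tuple[int, ...]]]:
    """event_id -> (label, category, hierarchy path as id tuple)."""
    out: dict[int, tuple[str, str, tuple[int, ...]]] = {}
    for row in vocabulary.itertuples(index=False):
        path = tuple(int(p) for p in str(row.hierarchy_path).split("/") if p != "")
        out[int(row.event_id)] = (str(row.label), str(row.category), path)
    return out


def clean_records(records: pd.DataFrame, admissions: pd.DataFrame) -> pd.DataFrame:
    """Drop records outside their admission window.

    Keeps only rows whose ``hadm_id`` exists in ``admissions`` and whose
    timestamp lies within ``[admit_time, min(discharge_time, death_time)]``;
    a record timestamped after discharge or death is an entry error.  Row
    order and identity of survivors are preserved.
    """
    _require_columns(records, ["hadm_id", "timestamp"], "event")
    _require_columns(admissions, ["hadm_id", "admit_time", "discharge_time"], "admission")
    if records.empty:
        return records.copy()
    adm = admissions.set_index("hadm_id")
    end = adm["discharge_time"]
    if "death_time" in adm.columns:
        death = pd.to_datetime(adm["death_time"])
        end = end.where(death.isna() | (end <= death), death)
    admit = records["hadm_id"].map(adm["admit_time"])
    window_end = records["hadm_id"].map(end)
    ts = pd.to_datetime(records["timestamp"])
    keep = admit.notna() & (ts >= admit) & (ts <= window_end)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("clean_records: dropped %d of %d records", dropped, len(records))
    return records.loc[keep].copy()


def filter_context(records: pd.DataFrame, include: set) -> pd.DataFrame:
    """Keep records whose event_id *or* category is in ``include`` (stable order)."""
    if not include:
        raise ValueError("include set must be nonempty")
    known = set(records["event_id"]).union(records.get("category", pd.Series(dtype=object)))
    unknown = {x for x in include if x not in known}
    if unknown:
        logger.warning("filter_context: ignoring unknown include entries %s", sorted(map(str, unknown)))
    keep = records["event_id"].isin(include)
    if "category" in records.columns:
        keep |= records["category"].isin(include)
    return records.loc[keep].copy()


def rollup_granularity(
    records: pd.DataFrame,
    vocabulary: pd.DataFrame,
    level: int,
) -> pd.DataFrame:
    """Replace each event_id with its hierarchy ancestor at ``level``.

    ``level`` indexes the root-to-leaf path (0 = root); ids whose path is
    shorter keep their deepest node, and ids without any hierarchy path pass
    through unchanged with a logged warning.
    """
    vocab = vocabulary_index(vocabulary)
    mapping: dict[int, int] = {}
    missing: list[int] = []
    for eid in pd.unique(records["event_id"]):
        info = vocab.get(int(eid))
        path = info[2] if info else ()
        if not path:
            missing.append(int(eid))
            mapping[int(eid)] = int(eid)
        else:
            mapping[int(eid)] = int(path[min(level, len(path) - 1)])
    if missing:
        logger.warning("rollup_granularity: no hierarchy path for ids %s; passed through", sorted(missing))
    out = records.copy()
    out["event_id"] = out["event_id"].map(mapping)
    return out


def bucket_time(records: pd.DataFrame, resolution: Resolution = "day") -> pd.DataFrame:
    """Attach a ``bucket`` column.

    ``day`` truncates timestamps to the calendar date; ``admission``
    collapses each admission to a single bucket (its earliest timestamp);
    ``none`` leaves each record in its own timestamp bucket.
    """
    out = records.copy()
    ts = pd.to_datetime(out["timestamp"])
    if resolution == "none":
        out["bucket"] = ts
    elif resolution == "day":
        out["bucket"] = ts.dt.normalize()
    elif resolution == "admission":
        out["bucket"] = out.groupby("hadm_id")["timestamp"].transform("min").dt.normalize()
    else:
        raise ValueError(f"unknown resolution {resolution!r}")
    return out


@dataclass
class SequenceRecord:
    """One ordered sequence: elements are ordered item tuples."""

    key: int
    elements: list[tuple[int, ...]]
    element_times: list[pd.Timestamp] = field(default_factory=list)


@dataclass
class SequenceDatabase:
    """Ordered element sequences over a finite event vocabulary."""

    sequences: list[SequenceRecord]
    vocabulary: dict[int, tuple[str, str, tuple[int, ...]]]
    unit: Unit = "admission"

    @property
    def n(self) -> int:
        return len(self.sequences)

    def keys(self) -> list[int]:
        return [s.key for s in self.sequences]

    def label_of(self, event_id: int) -> str:
        info = self.vocabulary.get(event_id)
        return info[0] if info else str(event_id)

    def id_of_label(self, label: str) -> int | None:
        for eid, (lab, _, _) in self.vocabulary.items():
            if lab == label:
                return eid
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "unit": self.unit,
                "vocabulary": {
                    str(eid): {"label": lab, "category": cat, "hierarchy_path": list(path)}
                    for eid, (lab, cat, path) in self.vocabulary.items()
                },
                "sequences": [
                    {
                        "key": s.key,
                        "elements": [list(el) for el in s.elements],
                        "element_times": [str(t) for t in s.element_times],
                    }
                    for s in self.sequences
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SequenceDatabase":
        d = json.loads(text)
        vocab = {
            int(eid): (v["label"], v["category"], tuple(v["hierarchy_path"]))
            for eid, v in d["vocabulary"].items()
        }
        seqs = [
            SequenceRecord(
                key=int(s["key"]),
                elements=[tuple(int(e) for e in el) for el in s["elements"]],
                element_times=[pd.Timestamp(t) for t in s["element_times"]],
            )
            for s in d["sequences"]
        ]
        return cls(sequences=seqs, vocabulary=vocab, unit=d["unit"])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "SequenceDatabase":
        return cls.from_json(Path(path).read_text())


def build_sequences(
    records: pd.DataFrame,
    unit: Unit = "admission",
    mode: Mode = "element-per-event",
    vocabulary: pd.DataFrame | dict | None = None,
) -> SequenceDatabase:
    """Convert (cleaned, optionally bucketed) records into a SequenceDatabase.

    One :class:`SequenceRecord` per unit key, rows ordered by
    (bucket, input row order, event_id).  ``element-per-event`` emits each
    record as its own singleton element; ``itemset-per-bucket`` merges
    same-bucket records into one ascending, de-duplicated itemset.
    """
    key_col = "subject_id" if unit == "patient" else "hadm_id"
    _require_columns(records, [key_col, "timestamp", "event_id"], "event")
    if isinstance(vocabulary, pd.DataFrame):
        vocab = vocabulary_index(vocabulary)
    elif isinstance(vocabulary, dict):
        vocab = vocabulary
    else:
        vocab = {
            int(e): (str(e), "", ())
            for e in pd.unique(records["event_id"])
        }

    df = records.copy()
    if "bucket" not in df.columns:
        df["bucket"] = pd.to_datetime(df["timestamp"])
    df["_row"] = range(len(df))
    df = df.sort_values(["bucket", "_row", "event_id"], kind="stable")

    sequences: list[SequenceRecord] = []
    for key, group in df.groupby(key_col, sort=True):
        if mode == "element-per-event":
            elements = [(int(e),) for e in group["event_id"]]
            times = list(group["bucket"])
        elif mode == "itemset-per-bucket":
            elements, times = [], []
            for bucket, sub in group.groupby("bucket", sort=True):
                items = tuple(sorted(set(int(e) for e in sub["event_id"])))
                elements.append(items)
                times.append(bucket)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if elements:
            sequences.append(SequenceRecord(key=int(key), elements=elements, element_times=times))
    return SequenceDatabase(sequences=sequences, vocabulary=vocab, unit=unit)
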