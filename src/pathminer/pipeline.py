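"""Config-driven orchestration of the full pathway-mining pipeline.

One YAML (or dict) configuration drives: generate-or-ingest -> clean ->
sequence construction -> closed-pattern mining -> pathway graph ->
cohort selection -> tensorization -> attention-LSTM training ->
interpretation exports.  Every intermediate artifact is written to the
output directory so any stage can be rerun in isolation, and a manifest
records the configuration echo, the seed, per-stage record/sample counts
and the held-out metrics; rerunning with the same config and seed
reproduces those counts exactly.

A single global seed fans out to per-stage seeds by fixed offsets
(synthetic +0, split +1, model init/shuffling +2, attention sampling +3).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import interpret, mining, model as model_mod, pathways, sequences, synthetic
from .errors import ConfigurationError, PathminerError

logger = logging.getLogger(__name__)

_SEED_SPLIT = 1
_SEED_MODEL = 2
_SEED_SAMPLE = 3


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; see module docstring."""

    outdir: str
    seed: int = 0
    synthetic: dict | None = None  # SyntheticConfig mapping
    inputs: dict | None = None  # {"events":..., "admissions":..., "vocabulary":..., "labels":...}
    unit: str = "admission"
    mode: str = "element-per-event"
    bucket: str = "day"
    include: list | None = None
    hierarchy_level: int | None = None
    min_support_rate: float = 0.25
    max_pattern_length: int | None = None
    pathway: list | None = None
    model: dict = field(default_factory=dict)
    top_k: int = 25

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' and 'inputs' must be configured"
            )
        if self.inputs is not None:
            for key in ("events", "admissions", "vocabulary"):
                if key not in self.inputs:
                    raise ConfigurationError(f"inputs: missing path for {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigurationError(f"inputs: file not found: {self.inputs[key]}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PathminerError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PathminerError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "counts": {},
        "metrics": {},
    }

    # --- ingest or generate -------------------------------------------------
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        scfg = synthetic.config_from_dict(syn)
        events, admissions, vocabulary, outcome_labels, truth = _stage("synthetic")(
            synthetic.generate_cohort
        )(scfg)
        synthetic.write_cohort(outdir / "cohort", events, admissions, vocabulary,
                               outcome_labels, truth)
    else:
        events = sequences.read_events(config.inputs["events"])
        admissions = sequences.read_admissions(config.inputs["admissions"])
        vocabulary = sequences.read_vocabulary(config.inputs["vocabulary"])
        if "labels" in config.inputs:
            lab = pd.read_csv(config.inputs["labels"])
            outcome_labels = lab.set_index(lab.columns[0])[lab.columns[1]]
        else:
            outcome_labels = None
    manifest["counts"]["raw_events"] = int(len(events))
    manifest["counts"]["admissions"] = int(len(admissions))

    # --- clean / filter / rollup / bucket -----------------------------------
    cleaned = _stage("clean")(sequences.clean_records)(events, admissions)
    manifest["counts"]["cleaned_events"] = int(len(cleaned))
    if config.include:
        cleaned = _stage("filter")(sequences.filter_context)(cleaned, set(config.include))
        manifest["counts"]["filtered_events"] = int(len(cleaned))
    if config.hierarchy_level is not None:
        cleaned = _stage("rollup")(sequences.rollup_granularity)(
            cleaned, vocabulary, config.hierarchy_level
        )
    bucketed = _stage("bucket")(sequences.bucket_time)(cleaned, config.bucket)

    # --- sequences ----------------------------------------------------------
    db = _stage("sequences")(sequences.build_sequences)(
        bucketed, unit=config.unit, mode=config.mode, vocabulary=vocabulary
    )
    db.write(outdir / "sequences.json")
    manifest["counts"]["sequences"] = db.n

    # --- mining -------------------------------------------------------------
    result = _stage("mining")(mining.mine_closed_patterns)(
        db, config.min_support_rate, max_length=config.max_pattern_length
    )
    result.write(outdir / "patterns.json")
    (outdir / "patterns.txt").write_text(result.to_table(db))
    manifest["counts"]["mined_patterns"] = len(result.patterns)

    if result.patterns:
        graph = _stage("pathway_graph")(pathways.merge_patterns)(result.patterns, db)
        pathways.write_sankey(graph, outdir / "sankey.json")
        manifest["counts"]["graph_nodes"] = len(graph.nodes)
        manifest["counts"]["graph_links"] = len(graph.links)

    # --- cohort selection ---------------------------------------------------
    train_labels = outcome_labels
    if config.pathway:
        selection = _stage("cohort")(pathways.match_pathway)(db, config.pathway)
        selection.write(outdir / "cohort_labels.csv")
        manifest["counts"]["cohort_size"] = selection.size
        if config.unit == "admission":
            train_labels = pd.Series(selection.labels)
        else:  # patient-level selection broadcast to admissions
            per_patient = pd.Series(selection.labels)
            train_labels = admissions.set_index("hadm_id")["subject_id"].map(per_patient)

    # --- tensor / model -----------------------------------------------------
    mcfg_dict = dict(config.model)
    mcfg_dict.setdefault("seed", config.seed + _SEED_MODEL)
    if "split_fractions" in mcfg_dict:
        mcfg_dict["split_fractions"] = tuple(mcfg_dict["split_fractions"])
    mcfg = model_mod.ModelConfig(**mcfg_dict)
    tensor = _stage("tensor")(model_mod.build_tensor)(
        bucketed, vocabulary, max_len=mcfg.max_len,
        labels=train_labels, admissions=admissions,
    )
    tensor.save(outdir / "tensor")
    manifest["counts"]["tensor_samples"] = tensor.n
    manifest["counts"]["tensor_features"] = tensor.F
    manifest["counts"]["label_prevalence"] = float(np.mean(tensor.labels))

    train, val, test = _stage("split")(model_mod.split_dataset)(
        tensor, mcfg.split_fractions, seed=config.seed + _SEED_SPLIT
    )
    manifest["counts"]["split_sizes"] = [train.n, val.n, test.n]
    trained = _stage("train")(model_mod.train_model)(train, val, mcfg)
    metrics = _stage("evaluate")(model_mod.evaluate)(trained, test)
    trained.metrics = metrics
    trained.save(outdir / "model")
    manifest["metrics"] = metrics

    # --- interpretation -----------------------------------------------------
    att = _stage("attention")(model_mod.extract_attention)(trained, tensor)
    att.save(outdir / "attention")
    payload = interpret.mean_attention(att, vocabulary=vocabulary)
    payload.write(outdir / "heatmap_mean.json")
    topk = interpret.top_k_variables(
        payload, k=config.top_k, group_by_category=True, vocabulary=vocabulary
    )
    interpret.write_topk(topk, outdir / "topk.json")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %s", manifest["counts"])
    return manifest
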