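import dataclasses

import numpy as np
import pandas as pd
import pytest

import pathminer as pm
from pathminer.sequences import SequenceDatabase, SequenceRecord


@pytest.fixture
def table1_records() -> pd.DataFrame:
    """The three-row worked example: two admissions of one subject, three
    events sharing a printed timestamp."""
    ts = pd.Timestamp("2189-12-24 07:15:00")
    return pd.DataFrame(
        {
            "subject_id": [18803, 18803, 18803],
            "hadm_id": [233, 233, 254],
            "timestamp": [ts, ts, ts],
            "event_id": [2, 6185, 30],
            "event_value": [1, 1, 1],
            "category": ["lab", "lab", "lab"],
        }
    )


def make_db(sequences: list[list[tuple[int, ...]]], unit: str = "admission") -> SequenceDatabase:
    """Build a SequenceDatabase from raw element lists, keys 0..n-1."""
    items = sorted({e for s in sequences for el in s for e in el})
    vocab = {e: (f"ev{e}", "lab", ()) for e in items}
    return SequenceDatabase(
        sequences=[SequenceRecord(key=k, elements=[tuple(el) for el in s]) for k, s in enumerate(sequences)],
        vocabulary=vocab,
        unit=unit,
    )


def random_db(rng: np.random.Generator, max_sequences: int = 8, max_len: int = 6,
              alphabet: int = 5, itemset_prob: float = 0.25) -> SequenceDatabase:
    """Random small database over a bounded alphabet, with occasional
    two-item elements."""
    n = int(rng.integers(2, max_sequences + 1))
    seqs = []
    for _ in range(n):
        length = int(rng.integers(1, max_len + 1))
        elements = []
        for _ in range(length):
            size = 1 + int(rng.random() < itemset_prob)
            elements.append(tuple(sorted(rng.choice(alphabet, size=size, replace=False) + 1)))
        seqs.append(elements)
    return make_db(seqs)


def sequences_from_cohort(events, admissions, vocabulary, unit="admission",
                          mode="element-per-event"):
    cleaned = pm.clean_records(events, admissions)
    bucketed = pm.bucket_time(cleaned, "day")
    return pm.build_sequences(bucketed, unit=unit, mode=mode, vocabulary=vocabulary)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared across read-only tests."""
    cfg = dataclasses.replace(
        pm.default_config(n_patients=200, seed=42), admissions_per_patient=(1, 1)
    )
    return pm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small but genuinely trained attention-LSTM with its data splits."""
    cfg = pm.strong_signal_config(n_patients=300, n_features=8, max_days=6, seed=5)
    events, admissions, vocab, labels, truth = pm.generate_cohort(cfg)
    cleaned = pm.bucket_time(pm.clean_records(events, admissions), "day")
    tensor = pm.build_tensor(cleaned, vocab, max_len=6, labels=labels, admissions=admissions)
    train, val, test = pm.split_dataset(tensor, seed=1)
    mcfg = pm.ModelConfig(lstm_units=16, max_len=6, epochs=4, seed=2)
    model = pm.train_model(train, val, mcfg)
    return model, tensor, test, truth
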