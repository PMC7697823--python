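"""Tensorization, splits, training, metrics and attention extraction."""

import numpy as np
import pandas as pd
import pytest

import pathminer as pm
from pathminer.errors import ArgumentError, ConfigurationError, ShapeError
from pathminer.model import (
    ModelConfig,
    _backward,
    _bce,
    _forward,
    _init_params,
    compute_metrics,
)


def _vocab(ids):
    return pd.DataFrame(
        {
            "event_id": ids,
            "label": [f"ev{i}" for i in ids],
            "category": ["lab"] * len(ids),
            "hierarchy_path": [""] * len(ids),
        }
    )


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "hadm_id", "timestamp", "event_id", "event_value", "category"],
    ).assign(timestamp=lambda d: pd.to_datetime(d["timestamp"]))


class TestBuildTensor:
    def test_three_day_stay_padded_to_max_len(self):
        rows = [(1, 1, f"2140-01-0{d}", 5, 1, "lab") for d in (1, 2, 3)]
        t = pm.build_tensor(_records(rows), _vocab([5, 6]), max_len=15)
        assert t.mask[0].tolist() == [1] * 3 + [0] * 12
        assert t.values[0, 3:].sum() == 0

    def test_long_stay_dropped_or_truncated(self):
        rows = [(1, 1, f"2140-01-{d:02d}", 5, 1, "lab") for d in range(1, 21)]
        dropped = pm.build_tensor(_records(rows), _vocab([5]), max_len=15, overflow="drop")
        assert dropped.n == 0
        trunc = pm.build_tensor(_records(rows), _vocab([5]), max_len=15, overflow="truncate")
        assert trunc.n == 1
        assert trunc.mask[0].sum() == 15
        assert trunc.values[0].sum() == 15  # one event per kept day

    def test_hand_computed_two_admission_tensor(self):
        rows = [
            (1, 1, "2140-01-01", 5, 1, "lab"),
            (1, 1, "2140-01-01", 6, 2, "lab"),
            (1, 1, "2140-01-02", 5, 1, "lab"),
            (2, 2, "2140-03-01", 7, 1, "lab"),
            (2, 2, "2140-03-03", 8, 4, "lab"),
        ]
        t = pm.build_tensor(_records(rows), _vocab([5, 6, 7, 8]), max_len=4)
        assert t.sample_keys == [1, 2]
        expected0 = np.zeros((4, 4))
        expected0[0, 0] = 1  # day 0 ev5
        expected0[0, 1] = 2  # day 0 ev6 value 2
        expected0[1, 0] = 1  # day 1 ev5
        expected1 = np.zeros((4, 4))
        expected1[0, 2] = 1  # day 0 ev7
        expected1[2, 3] = 4  # day 2 ev8 value 4
        np.testing.assert_array_equal(t.values[0], expected0)
        np.testing.assert_array_equal(t.values[1], expected1)
        assert t.mask.tolist() == [[1, 1, 0, 0], [1, 1, 1, 0]]

    def test_repeated_event_on_a_day_accumulates_count(self):
        rows = [(1, 1, "2140-01-01", 5, 1, "lab")] * 3
        t = pm.build_tensor(_records(rows), _vocab([5]), max_len=2)
        assert t.values[0, 0, 0] == 3

    def test_feature_overflow_raises(self):
        rows = [(1, 1, "2140-01-01", 5, 1, "lab")]
        with pytest.raises(ConfigurationError):
            pm.build_tensor(_records(rows), _vocab(list(range(300))), max_features=251)

    def test_tensor_save_load_round_trip(self, tmp_path):
        rows = [(1, 1, "2140-01-01", 5, 1, "lab"), (2, 2, "2140-01-01", 6, 1, "lab")]
        t = pm.build_tensor(_records(rows), _vocab([5, 6]), max_len=3,
                            labels={1: 1, 2: 0})
        t.save(tmp_path / "tensor")
        back = pm.FeatureTensor.load(tmp_path / "tensor")
        np.testing.assert_array_equal(back.values, t.values)
        np.testing.assert_array_equal(back.labels, t.labels)
        assert back.feature_index == t.feature_index


def _toy_tensor(n=100, T=5, F=4, seed=0, pos_ratio=0.4):
    rng = np.random.default_rng(seed)
    values = rng.random((n, T, F))
    lengths = rng.integers(1, T + 1, size=n)
    mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    values *= mask[..., None]
    labels = (np.arange(n) < int(pos_ratio * n)).astype(int)
    rng.shuffle(labels)
    return pm.FeatureTensor(
        values=values, mask=mask, feature_index={i: i for i in range(F)},
        labels=labels, sample_keys=list(range(n)),
    )


class TestSplitDataset:
    def test_hundred_samples_split_70_15_15(self):
        t = _toy_tensor(n=100, pos_ratio=0.4)
        tr, va, te = pm.split_dataset(t, (0.7, 0.15, 0.15), seed=0)
        assert (tr.n, va.n, te.n) == (70, 15, 15)

    def test_stratification_within_one_sample_of_overall_ratio(self):
        t = _toy_tensor(n=100, pos_ratio=0.4)
        for split, frac in zip(pm.split_dataset(t, seed=3), (0.7, 0.15, 0.15)):
            expected = 0.4 * split.n
            assert abs(split.labels.sum() - expected) <= 1

    def test_same_seed_reproduces_split_and_splits_are_disjoint(self):
        t = _toy_tensor(n=97)
        a = pm.split_dataset(t, seed=5)
        b = pm.split_dataset(t, seed=5)
        for x, y in zip(a, b):
            assert x.sample_keys == y.sample_keys
        all_keys = [k for s in a for k in s.sample_keys]
        assert sorted(all_keys) == list(range(97))

    def test_bad_fractions_rejected(self):
        t = _toy_tensor(n=10)
        with pytest.raises(ArgumentError):
            pm.split_dataset(t, (0.5, 0.4, 0.2))


class TestGradients:
    """Finite-difference check of the hand-written backward pass."""

    @pytest.mark.parametrize("cell", ["lstm", "rnn"])
    @pytest.mark.parametrize("sharing", ["per-timestep", "shared"])
    def test_analytic_gradient_matches_finite_differences(self, cell, sharing):
        rng = np.random.default_rng(0)
        B, T, F, H = 3, 4, 3, 5
        cfg = ModelConfig(lstm_units=H, max_len=T, cell=cell,
                          attention_weight_sharing=sharing, standardize=False)
        params = _init_params(cfg, F, rng)
        # nonzero attention weights so their gradient path is exercised
        params["Wa"] = rng.normal(scale=0.3, size=params["Wa"].shape)
        X = rng.normal(size=(B, T, F))
        M = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 1, 1, 1]], dtype=float)
        X *= M[..., None]
        y = np.array([1.0, 0.0, 1.0])
        mu, sd = np.zeros(F), np.ones(F)

        def loss(p):
            prob, _, _ = _forward(p, cfg, X, M, mu, sd)
            return _bce(prob, y)

        prob, _, cache = _forward(params, cfg, X, M, mu, sd, keep_cache=True)
        grads = _backward(params, cfg, cache, M, (prob - y) / B)
        eps = 1e-6
        for key in params:
            g = grads[key]
            flat = params[key].ravel()
            idxs = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                up = loss(params)
                flat[i] = orig - eps
                down = loss(params)
                flat[i] = orig
                fd = (up - down) / (2 * eps)
                assert abs(fd - g.ravel()[i]) < 1e-5 * max(1.0, abs(fd)), (key, i)


class TestTraining:
    def test_history_length_equals_epochs(self, tiny_trained_model):
        model, *_ = tiny_trained_model
        assert len(model.history) == model.config.epochs

    def test_single_class_labels_rejected(self):
        t = _toy_tensor(n=20)
        t.labels[:] = 1
        with pytest.raises(ArgumentError):
            pm.train_model(t, None, ModelConfig(lstm_units=4, max_len=5, epochs=1))

    def test_all_zero_features_give_chance_level_auroc(self):
        t = _toy_tensor(n=200, seed=4, pos_ratio=0.5)
        t.values[:] = 0.0
        tr, va, te = pm.split_dataset(t, seed=0)
        m = pm.train_model(tr, va, ModelConfig(lstm_units=8, max_len=5, epochs=3, seed=0))
        auroc = pm.evaluate(m, te)["auroc"]
        assert 0.3 < auroc < 0.7

    def test_same_seed_same_parameters(self):
        t = _toy_tensor(n=60, seed=2)
        cfg = ModelConfig(lstm_units=4, max_len=5, epochs=2, seed=9)
        m1 = pm.train_model(t, None, cfg)
        m2 = pm.train_model(t, None, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_model_save_load_preserves_predictions(self, tmp_path, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        model.save(tmp_path / "model")
        back = pm.TrainedModel.load(tmp_path / "model")
        np.testing.assert_allclose(pm.predict(back, tensor), pm.predict(model, tensor))


class TestPredict:
    def test_outputs_bounded_in_unit_interval(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        p = pm.predict(model, tensor)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_permuting_samples_permutes_outputs(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        perm = np.random.default_rng(0).permutation(tensor.n)
        p = pm.predict(model, tensor)
        p_perm = pm.predict(model, tensor.subset(perm))
        np.testing.assert_allclose(p_perm, p[perm])

    def test_perturbing_padded_days_leaves_output_unchanged(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        base = pm.predict(model, tensor)
        noisy = tensor.subset(np.arange(tensor.n))
        noisy.values = noisy.values.copy()
        rng = np.random.default_rng(1)
        noisy.values += (1 - noisy.mask[..., None]) * rng.normal(size=noisy.values.shape)
        np.testing.assert_allclose(pm.predict(model, noisy), base, atol=1e-12)

    def test_feature_mismatch_raises_shape_error(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        bad = pm.FeatureTensor(
            values=tensor.values[:, :, :-1],
            mask=tensor.mask,
            feature_index={k: v for k, v in list(tensor.feature_index.items())[:-1]},
            labels=tensor.labels,
            sample_keys=tensor.sample_keys,
        )
        with pytest.raises(ShapeError):
            pm.predict(model, bad)


def _brute_force_auroc(labels, scores):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    @pytest.mark.parametrize(
        "labels,scores,auroc,f1",
        [
            ((1, 1, 0, 0), (0.9, 0.8, 0.3, 0.2), 1.0, 1.0),
            ((1, 0, 1, 0), (0.5, 0.5, 0.5, 0.5), 0.5, None),
            ((1, 1, 1, 0, 0, 0), (0.9, 0.8, 0.4, 0.5, 0.3, 0.2), 8 / 9, None),
        ],
    )
    def test_frozen_fixtures(self, labels, scores, auroc, f1):
        m = compute_metrics(np.array(labels), np.array(scores))
        assert m["auroc"] == pytest.approx(auroc)
        if f1 is not None:
            assert m["f1"] == pytest.approx(f1)

    def test_agrees_with_pairwise_concordance_on_random_scores(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            m = compute_metrics(labels, scores)
            assert m["auroc"] == pytest.approx(_brute_force_auroc(labels, scores))

    def test_single_class_test_set_rejected(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        single = tensor.subset(np.flatnonzero(tensor.labels == 1))
        with pytest.raises(ArgumentError):
            pm.evaluate(model, single)


class TestAttention:
    def test_unmasked_rows_sum_to_one_masked_rows_to_zero(self, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        att = pm.extract_attention(model, tensor)
        sums = att.weights.sum(axis=2)
        np.testing.assert_allclose(sums[att.mask == 1], 1.0, atol=1e-6)
        assert np.all(sums[att.mask == 0] == 0.0)
        assert np.all(att.weights >= 0)

    def test_attention_round_trip(self, tmp_path, tiny_trained_model):
        model, tensor, *_ = tiny_trained_model
        att = pm.extract_attention(model, tensor)
        att.save(tmp_path / "att")
        back = pm.AttentionMap.load(tmp_path / "att")
        np.testing.assert_array_equal(back.weights, att.weights)
        assert back.sample_keys == att.sample_keys

    def test_causal_feature_gets_top_mean_attention(self, tiny_trained_model):
        model, tensor, test, truth = tiny_trained_model
        att = pm.extract_attention(model, tensor)
        payload = pm.mean_attention(att)
        col = tensor.feature_index[next(iter(truth.causal_event_ids))]
        ranking = np.argsort(-payload.matrix.sum(axis=0))
        assert col in ranking[:3]


class TestBaselineComparison:
    def test_plain_rnn_does_not_beat_lstm_beyond_noise(self):
        cfg = pm.strong_signal_config(n_patients=600, n_features=10, max_days=8, seed=21)
        events, admissions, vocab, labels, _ = pm.generate_cohort(cfg)
        cleaned = pm.bucket_time(pm.clean_records(events, admissions), "day")
        tensor = pm.build_tensor(cleaned, vocab, max_len=8, labels=labels, admissions=admissions)
        tr, va, te = pm.split_dataset(tensor, seed=0)
        scores = {}
        for cell in ("lstm", "rnn"):
            m = pm.train_model(tr, va, ModelConfig(lstm_units=32, max_len=8,
                                                   epochs=8, seed=3, cell=cell))
            scores[cell] = pm.evaluate(m, te)["auroc"]
        assert scores["rnn"] <= scores["lstm"] + 0.05
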