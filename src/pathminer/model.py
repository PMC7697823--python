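"""Attention-LSTM outcome prediction on per-day EHR feature tensors.

The predictor consumes a 3-D tensor — admissions x hospital days x event
features — with a prefix mask marking true stay length.  Per unmasked day
``k`` an attention vector is computed from the day's features,

    a_k = softmax(W_k . x_k),

and the day's input is re-weighted elementwise, ``x~_k = x_k * a_k``,
before entering an LSTM whose final hidden state feeds a sigmoid output
unit predicting the binary outcome.  The attention weights ``a_k`` are
nonnegative, sum to one over features at each unmasked day, and are
extracted after training as the model's per-day, per-feature saliency map.
``W_k`` is a separate learned matrix per day by default (weight sharing
across days is available), and a plain tanh recurrence can replace the
LSTM for baseline comparisons.

The network, its gradients and the Adam optimizer are implemented directly
in numpy: the model is small (tens of timesteps, at most a few hundred
features) and a self-contained implementation keeps the attention
machinery fully inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .errors import ArgumentError, ConfigurationError, ShapeError
from .sequences import vocabulary_index
from .synthetic import leaf_event_ids as _vocab_leaves
from .synthetic import VocabEntry

logger = logging.getLogger(__name__)

DEFAULT_MAX_TIMESTEPS = 15
DEFAULT_MAX_FEATURES = 251


# ---------------------------------------------------------------- tensors


@dataclass
class FeatureTensor:
    """samples x timesteps x features array with prefix mask and labels."""

    values: np.ndarray  # [N, T, F] float
    mask: np.ndarray  # [N, T] float {0,1}, prefix of ones
    feature_index: dict[int, int]  # event_id -> column
    labels: np.ndarray  # [N] int {0,1}
    sample_keys: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def F(self) -> int:
        return self.values.shape[2]

    def subset(self, indices: np.ndarray) -> "FeatureTensor":
        return FeatureTensor(
            values=self.values[indices],
            mask=self.mask[indices],
            feature_index=self.feature_index,
            labels=self.labels[indices],
            sample_keys=[self.sample_keys[i] for i in indices] if self.sample_keys else [],
        )

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), values=self.values, mask=self.mask, labels=self.labels)
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "feature_index": {str(k): v for k, v in self.feature_index.items()},
                    "sample_keys": self.sample_keys,
                }
            )
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureTensor":
        prefix = Path(prefix)
        arrays = np.load(prefix.with_suffix(".npz"))
        side = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            values=arrays["values"],
            mask=arrays["mask"],
            feature_index={int(k): v for k, v in side["feature_index"].items()},
            labels=arrays["labels"],
            sample_keys=list(side["sample_keys"]),
        )


def build_tensor(
    records: pd.DataFrame,
    vocabulary: pd.DataFrame,
    max_len: int = DEFAULT_MAX_TIMESTEPS,
    overflow: str = "truncate",
    labels: Mapping[int, int] | pd.Series | None = None,
    admissions: pd.DataFrame | None = None,
    max_features: int = DEFAULT_MAX_FEATURES,
) -> FeatureTensor:
    """Tensorize cleaned records: one sample per admission, one row per day.

    Day ``t``, feature ``f`` holds the summed event value (an occurrence
    count for binary events) of event ``f`` on hospital day ``t``, counted
    from the admission date when ``admissions`` is given, else from the
    admission's first event.  Stays longer than ``max_len`` days are
    truncated to the first ``max_len`` days (``overflow="truncate"``) or
    removed (``overflow="drop"``); shorter stays are zero-padded with a
    zero mask.
    """
    if overflow not in ("truncate", "drop"):
        raise ArgumentError("overflow must be 'truncate' or 'drop'")
    vocab_df = vocabulary
    entries = [
        VocabEntry(int(r.event_id), str(r.label), str(r.category),
                   tuple(int(p) for p in str(r.hierarchy_path).split("/") if p != "")
                   if "hierarchy_path" in vocab_df.columns else ())
        for r in vocab_df.itertuples(index=False)
    ]
    feature_ids = _vocab_leaves(entries)
    if len(feature_ids) > max_features:
        raise ConfigurationError(
            f"feature count {len(feature_ids)} exceeds max_features={max_features}"
        )
    feature_index = {eid: i for i, eid in enumerate(feature_ids)}

    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    unknown = set(df["event_id"]) - set(feature_index)
    if unknown:
        logger.warning("build_tensor: dropping %d event ids absent from vocabulary leaves", len(unknown))
        df = df[df["event_id"].isin(feature_index)]

    admit_dates = None
    if admissions is not None:
        admit_dates = (
            admissions.set_index("hadm_id")["admit_time"].pipe(pd.to_datetime).dt.normalize()
        )

    samples: list[tuple[int, np.ndarray, int]] = []
    for hadm, group in df.groupby("hadm_id", sort=True):
        dates = group["timestamp"].dt.normalize()
        start = admit_dates.loc[hadm] if admit_dates is not None and hadm in admit_dates.index else dates.min()
        days = ((dates - start).dt.days).to_numpy()
        n_days = int(days.max()) + 1
        if n_days > max_len:
            if overflow == "drop":
                continue
            keep = days < max_len
            group, days = group[keep], days[keep]
            n_days = max_len
        mat = np.zeros((max_len, len(feature_ids)))
        vals = pd.to_numeric(group.get("event_value", 1), errors="coerce").fillna(1.0).to_numpy()
        for d, eid, v in zip(days, group["event_id"].to_numpy(), vals):
            mat[int(d), feature_index[int(eid)]] += v
        samples.append((int(hadm), mat, n_days))

    n = len(samples)
    values = np.zeros((n, max_len, len(feature_ids)))
    mask = np.zeros((n, max_len))
    keys = []
    for i, (hadm, mat, n_days) in enumerate(samples):
        values[i] = mat
        mask[i, :n_days] = 1.0
        keys.append(hadm)
    if labels is not None:
        lab = np.array([int(labels[k]) for k in keys])
    else:
        lab = np.zeros(n, dtype=int)
    return FeatureTensor(values=values, mask=mask, feature_index=feature_index,
                         labels=lab, sample_keys=keys)


def split_dataset(
    tensor: FeatureTensor,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> tuple[FeatureTensor, FeatureTensor, FeatureTensor]:
    """Disjoint, exhaustive, label-stratified train/validation/test split.

    Within each class, a seeded shuffle is apportioned by cumulative
    rounding, so split sizes match the fractions to within rounding and the
    class ratio of each split stays within one sample of the overall ratio.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ArgumentError("split fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(tensor.labels):
        idx = np.flatnonzero(tensor.labels == cls)
        rng.shuffle(idx)
        bounds = np.round(np.cumsum(fractions) * len(idx)).astype(int)
        parts[0].extend(idx[: bounds[0]])
        parts[1].extend(idx[bounds[0]: bounds[1]])
        parts[2].extend(idx[bounds[1]:])
    out = []
    for p in parts:
        p = np.sort(np.array(p, dtype=int))
        sub = tensor.subset(p)
        if len(np.unique(sub.labels)) < 2:
            logger.warning("split_dataset: a split contains a single class")
        out.append(sub)
    return tuple(out)


# ---------------------------------------------------------------- model


@dataclass
class ModelConfig:
    """Hyperparameters of the attention recurrent predictor.

    Defaults follow common practice for this architecture: 128 LSTM units,
    Adam (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8), batch 64, 10 epochs,
    0.7/0.15/0.15 splits, F1 threshold 0.5.  ``batch_size=256, epochs=20``
    is the alternative preset.
    """

    lstm_units: int = 128
    max_len: int = DEFAULT_MAX_TIMESTEPS
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 64
    epochs: int = 10
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0
    attention_weight_sharing: str = "per-timestep"  # or "shared"
    cell: str = "lstm"  # or "rnn"
    f1_threshold: float = 0.5
    standardize: bool = True

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9 or any(
            f <= 0 for f in self.split_fractions
        ):
            raise ConfigurationError("split_fractions must be positive and sum to 1")
        if self.attention_weight_sharing not in ("per-timestep", "shared"):
            raise ConfigurationError("attention_weight_sharing must be 'per-timestep' or 'shared'")
        if self.cell not in ("lstm", "rnn"):
            raise ConfigurationError("cell must be 'lstm' or 'rnn'")
        if self.lstm_units < 1 or self.max_len < 1:
            raise ConfigurationError("lstm_units and max_len must be >= 1")


@dataclass
class AttentionMap:
    """Per-sample [T x F] attention weights; unmasked rows sum to 1."""

    weights: np.ndarray  # [N, T, F]
    mask: np.ndarray  # [N, T]
    feature_index: dict[int, int]
    sample_keys: list[int] = field(default_factory=list)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"), weights=self.weights, mask=self.mask)
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "feature_index": {str(k): v for k, v in self.feature_index.items()},
                    "sample_keys": self.sample_keys,
                }
            )
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "AttentionMap":
        prefix = Path(prefix)
        arrays = np.load(prefix.with_suffix(".npz"))
        side = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            weights=arrays["weights"],
            mask=arrays["mask"],
            feature_index={int(k): v for k, v in side["feature_index"].items()},
            sample_keys=list(side["sample_keys"]),
        )


@dataclass
class TrainedModel:
    params: dict[str, np.ndarray]
    config: ModelConfig
    feature_index: dict[int, int]
    mu: np.ndarray  # per-feature standardization, from the training split
    sd: np.ndarray
    history: list[dict] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "params.npz", mu=self.mu, sd=self.sd, **self.params)
        (outdir / "model.json").write_text(
            json.dumps(
                {
                    "config": asdict(self.config),
                    "feature_index": {str(k): v for k, v in self.feature_index.items()},
                    "history": self.history,
                    "metrics": self.metrics,
                }
            )
        )

    @classmethod
    def load(cls, outdir: str | Path) -> "TrainedModel":
        outdir = Path(outdir)
        arrays = dict(np.load(outdir / "params.npz"))
        side = json.loads((outdir / "model.json").read_text())
        mu = arrays.pop("mu")
        sd = arrays.pop("sd")
        cfg = side["config"]
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        return cls(
            params=arrays,
            config=ModelConfig(**cfg),
            feature_index={int(k): v for k, v in side["feature_index"].items()},
            mu=mu,
            sd=sd,
            history=side["history"],
            metrics=side["metrics"],
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_params(config: ModelConfig, F: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    H = config.lstm_units
    T = config.max_len
    n_att = T if config.attention_weight_sharing == "per-timestep" else 1
    gate_mult = 4 if config.cell == "lstm" else 1

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    params = {
        # zero attention weights start from uniform attention
        "Wa": np.zeros((n_att, F, F)),
        "Wx": glorot((F, gate_mult * H)),
        "Wh": glorot((H, gate_mult * H)),
        "b": np.zeros(gate_mult * H),
        "w_out": glorot((H, 1))[:, 0],
        "b_out": np.zeros(1),
    }
    if config.cell == "lstm":
        params["b"][H: 2 * H] = 1.0  # forget-gate bias
    return params


def _forward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    X: np.ndarray,
    M: np.ndarray,
    mu: np.ndarray,
    sd: np.ndarray,
    keep_cache: bool = False,
):
    """Forward pass; returns (probabilities, attention [B,T,F], cache)."""
    B, T, F = X.shape
    H = config.lstm_units
    Xs = ((X - mu) / sd) * M[..., None]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    att = np.zeros((B, T, F))
    cache = {"steps": [], "Xs": Xs} if keep_cache else None
    shared = config.attention_weight_sharing == "shared"
    for k in range(T):
        Wk = params["Wa"][0 if shared else k]
        z = Xs[:, k] @ Wk.T
        a_raw = _softmax(z)
        m = M[:, k: k + 1]
        a = a_raw * m
        att[:, k] = a
        xt = Xs[:, k] * a
        h_prev, c_prev = h, c
        if config.cell == "lstm":
            gates = xt @ params["Wx"] + h_prev @ params["Wh"] + params["b"]
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H: 2 * H])
            g = np.tanh(gates[:, 2 * H: 3 * H])
            o = _sigmoid(gates[:, 3 * H:])
            c_new = f * c_prev + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            c = m * c_new + (1 - m) * c_prev
            h = m * h_new + (1 - m) * h_prev
            if keep_cache:
                cache["steps"].append(
                    dict(a_raw=a_raw, xt=xt, i=i, f=f, g=g, o=o, hc=hc,
                         c_prev=c_prev, h_prev=h_prev, m=m)
                )
        else:
            pre = xt @ params["Wx"] + h_prev @ params["Wh"] + params["b"]
            h_new = np.tanh(pre)
            h = m * h_new + (1 - m) * h_prev
            if keep_cache:
                cache["steps"].append(dict(a_raw=a_raw, xt=xt, h_new=h_new,
                                           h_prev=h_prev, m=m))
    logit = h @ params["w_out"] + params["b_out"][0]
    prob = _sigmoid(logit)
    if keep_cache:
        cache["h_final"] = h
    return prob, att, cache


def _backward(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    cache: dict,
    M: np.ndarray,
    dlogit: np.ndarray,
) -> dict[str, np.ndarray]:
    B, T, F = cache["Xs"].shape
    H = config.lstm_units
    Xs = cache["Xs"]
    shared = config.attention_weight_sharing == "shared"
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["w_out"] = cache["h_final"].T @ dlogit
    grads["b_out"] = np.array([dlogit.sum()])
    dh = dlogit[:, None] * params["w_out"][None, :]
    dc = np.zeros((B, H))
    for k in reversed(range(T)):
        s = cache["steps"][k]
        m = s["m"]
        dh_new = dh * m
        dh_carry = dh * (1 - m)
        if config.cell == "lstm":
            dc_new = dc * m
            dc_carry = dc * (1 - m)
            do = dh_new * s["hc"]
            dc_new = dc_new + dh_new * s["o"] * (1 - s["hc"] ** 2)
            di = dc_new * s["g"]
            dg = dc_new * s["i"]
            df = dc_new * s["c_prev"]
            dc = dc_new * s["f"] + dc_carry
            dgates = np.concatenate(
                [
                    di * s["i"] * (1 - s["i"]),
                    df * s["f"] * (1 - s["f"]),
                    dg * (1 - s["g"] ** 2),
                    do * s["o"] * (1 - s["o"]),
                ],
                axis=1,
            )
        else:
            dpre = dh_new * (1 - s["h_new"] ** 2)
            dgates = dpre
        grads["Wx"] += s["xt"].T @ dgates
        grads["Wh"] += s["h_prev"].T @ dgates
        grads["b"] += dgates.sum(axis=0)
        dxt = dgates @ params["Wx"].T
        dh = dgates @ params["Wh"].T + dh_carry
        # attention backward: xt = Xs_k * (a_raw * m)
        da_raw = dxt * Xs[:, k] * m
        a_raw = s["a_raw"]
        dz = a_raw * (da_raw - (da_raw * a_raw).sum(axis=1, keepdims=True))
        grads["Wa"][0 if shared else k] += dz.T @ Xs[:, k]
    return grads


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_model(
    train: FeatureTensor,
    val: FeatureTensor | None,
    config: ModelConfig,
) -> TrainedModel:
    """Fit the attention recurrent predictor with Adam on binary cross-entropy.

    Per-feature standardization statistics are computed on the unmasked
    entries of the training split and stored with the model.  All
    randomness (initialization, shuffling) flows from ``config.seed``.
    """
    config.validate()
    y = train.labels.astype(float)
    if len(np.unique(train.labels)) < 2:
        raise ArgumentError("training labels contain a single class")
    if train.T != config.max_len:
        raise ShapeError(
            f"tensor has {train.T} timesteps but config.max_len={config.max_len}"
        )
    rng = np.random.default_rng(config.seed)
    F = train.F
    X, M = train.values, train.mask

    if config.standardize:
        w = M[..., None]
        tot = w.sum(axis=(0, 1))
        mu = (X * w).sum(axis=(0, 1)) / np.maximum(tot, 1.0)
        var = (((X - mu) ** 2) * w).sum(axis=(0, 1)) / np.maximum(tot, 1.0)
        sd = np.maximum(np.sqrt(var), 1e-6)
    else:
        mu = np.zeros(F)
        sd = np.ones(F)

    params = _init_params(config, F, rng)
    m_adam = {k: np.zeros_like(v) for k, v in params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in params.items()}
    t_step = 0
    history: list[dict] = []
    n = train.n
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            Xb, Mb, yb = X[idx], M[idx], y[idx]
            prob, _, cache = _forward(params, config, Xb, Mb, mu, sd, keep_cache=True)
            losses.append(_bce(prob, yb) * len(idx))
            dlogit = (prob - yb) / len(idx)
            grads = _backward(params, config, cache, Mb, dlogit)
            t_step += 1
            for key in params:
                g = grads[key]
                m_adam[key] = config.beta1 * m_adam[key] + (1 - config.beta1) * g
                v_adam[key] = config.beta2 * v_adam[key] + (1 - config.beta2) * g * g
                mhat = m_adam[key] / (1 - config.beta1 ** t_step)
                vhat = v_adam[key] / (1 - config.beta2 ** t_step)
                params[key] = params[key] - config.learning_rate * mhat / (
                    np.sqrt(vhat) + config.epsilon
                )
        entry = {"epoch": epoch, "train_loss": float(np.sum(losses) / n)}
        if val is not None and val.n > 0:
            vprob, _, _ = _forward(params, config, val.values, val.mask, mu, sd)
            entry["val_loss"] = _bce(vprob, val.labels.astype(float))
            if len(np.unique(val.labels)) > 1:
                entry["val_auroc"] = float(roc_auc_score(val.labels, vprob))
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
    return TrainedModel(
        params=params,
        config=config,
        feature_index=train.feature_index,
        mu=mu,
        sd=sd,
        history=history,
    )


def _check_compatible(model: TrainedModel, tensor: FeatureTensor) -> None:
    if tensor.F != len(model.feature_index) or tensor.feature_index != model.feature_index:
        raise ShapeError("tensor feature_index is incompatible with the model")
    if tensor.T != model.config.max_len:
        raise ShapeError(
            f"tensor has {tensor.T} timesteps; model expects {model.config.max_len}"
        )


def predict(model: TrainedModel, tensor: FeatureTensor, batch_size: int = 1024) -> np.ndarray:
    """Per-sample outcome probabilities in [0, 1]."""
    _check_compatible(model, tensor)
    out = []
    for start in range(0, tensor.n, batch_size):
        sl = slice(start, start + batch_size)
        prob, _, _ = _forward(
            model.params, model.config, tensor.values[sl], tensor.mask[sl],
            model.mu, model.sd,
        )
        out.append(prob)
    return np.concatenate(out) if out else np.zeros(0)


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUROC (rank-based, ties count one half) and F1 at ``threshold``."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ArgumentError("AUROC is undefined for a single-class label set")
    pred = (np.asarray(scores) >= threshold).astype(int)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
    }


def evaluate(model: TrainedModel, test: FeatureTensor) -> dict[str, float]:
    """Held-out AUROC and F1 of a trained model."""
    prob = predict(model, test)
    return compute_metrics(test.labels, prob, model.config.f1_threshold)


def extract_attention(model: TrainedModel, tensor: FeatureTensor, batch_size: int = 1024) -> AttentionMap:
    """Per-sample [T x F] attention weights; masked days carry zero weight."""
    _check_compatible(model, tensor)
    maps = []
    for start in range(0, tensor.n, batch_size):
        sl = slice(start, start + batch_size)
        _, att, _ = _forward(
            model.params, model.config, tensor.values[sl], tensor.mask[sl],
            model.mu, model.sd,
        )
        maps.append(att)
    weights = np.concatenate(maps) if maps else np.zeros((0, tensor.T, tensor.F))
    return AttentionMap(
        weights=weights,
        mask=tensor.mask.copy(),
        feature_index=tensor.feature_index,
        sample_keys=list(tensor.sample_keys),
    )
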