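"""A small recurrent sequence classifier for per-visit laboratory features.

The network unrolls over a patient's visit sequence.  Each hidden layer *l*
updates as

    h_t^l = tanh(W_l x_t^l + U_l h_{t-1}^l + b_l)

where x_t^1 is the standardised feature vector of visit *t* and x_t^l (l>1)
is the layer below's activation.  At the final visit a two-unit softmax head
turns the top activation into a CKD probability (component 0 is p(CKD)).
Training minimises mean cross-entropy by backpropagation through time with
RMSprop updates and inverted dropout on hidden activations (training only).

Everything is plain numpy and deterministic given the configured seed; the
analytic BPTT gradients are verified against central finite differences in
the test suite.

Also here: the greedy forward ("bottom-up") / backward ("top-down") wrapper
feature selection and the cross-validated architecture screen, both scored by
F1 at the p = 0.5 cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .ehr_core import CKDStatus, ConfigurationError, LabeledRecord

__all__ = [
    "FeatureSpec",
    "NetConfig",
    "SequenceSample",
    "TrainedNet",
    "TrainingError",
    "DEFAULT_FEATURES",
    "fit_feature_spec",
    "build_sequences",
    "init_params",
    "forward",
    "predict_proba",
    "loss_and_grads",
    "train",
    "cross_validated_f1",
    "wrapper_feature_selection",
    "architecture_screen",
    "count_params",
    "save_net",
    "load_net",
]

#: the six default model features, in canonical order.
DEFAULT_FEATURES = ("creatinine", "BUN", "USG", "urine_protein", "weight", "age")

#: softmax output component indices.
CLASS_CKD, CLASS_NOCKD = 0, 1


class TrainingError(ValueError):
    """Training preconditions are violated (e.g. a single-class sample set)."""


@dataclass
class FeatureSpec:
    """Ordered feature names plus the training-set standardisation scaler."""

    names: tuple[str, ...]
    scaler: dict[str, tuple[float, float]]  # name -> (mean, sd)
    weight_fallback: float = math.nan  # training-cohort median weight

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("need at least one feature")
        for name in self.names:
            if name in self.scaler and self.scaler[name][1] <= 0:
                raise ConfigurationError(f"feature {name!r} has non-positive scaler SD")


@dataclass
class NetConfig:
    hidden_layers: tuple[int, ...] = (5, 3, 3)
    dropout: float = 0.2
    epochs: int = 8
    learning_rate: float = 1e-3
    rmsprop_decay: float = 0.9
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(w) for w in self.hidden_layers)
        if not self.hidden_layers or min(self.hidden_layers) < 1:
            raise ValueError("hidden layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SequenceSample:
    """One standardised visit sequence: x is (T, n_features); label 1 = CKD."""

    x: np.ndarray
    label: int
    provenance: tuple[str, int] = ("", 0)


@dataclass
class TrainedNet:
    params: dict[str, np.ndarray]
    feature_spec: FeatureSpec
    config: NetConfig
    loss_trace: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def _raw_feature_matrix(
    record: LabeledRecord, names: Sequence[str], weight_fallback: float
) -> np.ndarray:
    rows = []
    last_weight = None
    for visit in record.usable_visits:
        row = []
        for name in names:
            if name == "age":
                row.append(visit.age_years)
            elif name == "weight":
                if visit.weight_kg is not None:
                    last_weight = visit.weight_kg
                w = last_weight if last_weight is not None else weight_fallback
                row.append(w)
            else:
                if name not in visit.analytes:
                    raise ConfigurationError(
                        f"feature {name!r} missing at age {visit.age_years} of "
                        f"{record.patient_id}; impute before building sequences"
                    )
                row.append(visit.analytes[name])
        rows.append(row)
    return np.asarray(rows, dtype=float)


def fit_feature_spec(
    records: Sequence[LabeledRecord], names: Sequence[str] = DEFAULT_FEATURES
) -> FeatureSpec:
    """Fit the per-feature standardisation scaler on (training) records."""
    weights = [
        v.weight_kg for r in records for v in r.usable_visits if v.weight_kg is not None
    ]
    fallback = float(np.median(weights)) if weights else math.nan
    mats = [_raw_feature_matrix(r, names, fallback) for r in records if r.usable_visits]
    if not mats:
        raise ValueError("no visits to fit the scaler on")
    stacked = np.vstack(mats)
    scaler = {}
    for i, name in enumerate(names):
        col = stacked[:, i]
        sd = float(np.std(col))
        if sd <= 1e-12:
            raise ConfigurationError(f"feature {name!r} has zero variance; cannot scale")
        scaler[name] = (float(np.mean(col)), sd)
    return FeatureSpec(names=tuple(names), scaler=scaler, weight_fallback=fallback)


def build_sequences(
    records: Sequence[LabeledRecord], spec: FeatureSpec
) -> list[SequenceSample]:
    """One standardised SequenceSample per record (CKD=1, NO_CKD=0).

    Missing weight is carried forward from the most recent prior visit, else
    the training-cohort median.  PROBABLE_CKD (and EXCLUDED) records are
    refused: they are never modelled.
    """
    samples = []
    for rec in records:
        if rec.status not in (CKDStatus.CKD, CKDStatus.NO_CKD):
            raise ValueError(
                f"record {rec.patient_id} has status {rec.status}; only CKD/NO_CKD "
                "records can be turned into sequences"
            )
        if not rec.usable_visits:
            raise ValueError(f"record {rec.patient_id} has no usable visits")
        raw = _raw_feature_matrix(rec, spec.names, spec.weight_fallback)
        mean = np.array([spec.scaler[n][0] for n in spec.names])
        sd = np.array([spec.scaler[n][1] for n in spec.names])
        prov = rec.provenance or (rec.patient_id, 0)
        samples.append(
            SequenceSample(
                x=(raw - mean) / sd,
                label=1 if rec.status == CKDStatus.CKD else 0,
                provenance=prov,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Network core
# ---------------------------------------------------------------------------

def init_params(
    config: NetConfig, n_features: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Small fan-in-scaled uniform initialisation, fixed by the rng state."""
    widths = config.hidden_layers
    params: dict[str, np.ndarray] = {}
    fan_in = n_features
    for l, w in enumerate(widths):
        params[f"W{l}"] = rng.uniform(-1, 1, size=(w, fan_in)) / math.sqrt(fan_in)
        params[f"U{l}"] = rng.uniform(-1, 1, size=(w, w)) / math.sqrt(w)
        params[f"b{l}"] = np.zeros(w)
        fan_in = w
    params["V"] = rng.uniform(-1, 1, size=(2, widths[-1])) / math.sqrt(widths[-1])
    params["c"] = np.zeros(2)
    return params


def _forward_sample(
    params: dict[str, np.ndarray],
    widths: tuple[int, ...],
    x: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Unroll the net over one sequence; returns (softmax probs, cache)."""
    T = x.shape[0]
    L = len(widths)
    h = [[None] * T for _ in range(L)]  # tanh activations
    hd = [[None] * T for _ in range(L)]  # post-dropout activations
    masks = [[None] * T for _ in range(L)]
    prev = [np.zeros(w) for w in widths]
    for t in range(T):
        inp = x[t]
        for l in range(L):
            a = params[f"W{l}"] @ inp + params[f"U{l}"] @ prev[l] + params[f"b{l}"]
            act = np.tanh(a)
            if dropout > 0.0:
                mask = (rng.random(act.shape) >= dropout) / (1.0 - dropout)
                dropped = act * mask
            else:
                mask = None
                dropped = act
            h[l][t], hd[l][t], masks[l][t] = act, dropped, mask
            prev[l] = dropped
            inp = dropped
    logits = params["V"] @ hd[L - 1][T - 1] + params["c"]
    z = logits - logits.max()
    e = np.exp(z)
    probs = e / e.sum()
    cache = {"h": h, "hd": hd, "masks": masks, "probs": probs, "x": x}
    return probs, cache


def _backward_sample(
    params: dict[str, np.ndarray],
    widths: tuple[int, ...],
    cache: dict,
    target: int,
    grads: dict[str, np.ndarray],
) -> float:
    """Accumulate BPTT gradients of the cross-entropy into ``grads``;
    returns the sample loss.  ``target`` is the softmax class index."""
    x = cache["x"]
    h, hd, masks, probs = cache["h"], cache["hd"], cache["masks"], cache["probs"]
    T = x.shape[0]
    L = len(widths)
    loss = -math.log(max(probs[target], 1e-300))

    dlogits = probs.copy()
    dlogits[target] -= 1.0
    grads["V"] += np.outer(dlogits, hd[L - 1][T - 1])
    grads["c"] += dlogits

    dhd = [[None] * T for _ in range(L)]
    dhd[L - 1][T - 1] = params["V"].T @ dlogits
    for t in range(T - 1, -1, -1):
        for l in range(L - 1, -1, -1):
            d = dhd[l][t]
            if d is None:
                continue
            if masks[l][t] is not None:
                d = d * masks[l][t]
            da = d * (1.0 - h[l][t] ** 2)
            inp = x[t] if l == 0 else hd[l - 1][t]
            grads[f"W{l}"] += np.outer(da, inp)
            if t > 0:
                grads[f"U{l}"] += np.outer(da, hd[l][t - 1])
            grads[f"b{l}"] += da
            if l > 0:
                prev_d = dhd[l - 1][t]
                dhd[l - 1][t] = (params[f"W{l}"].T @ da) + (0 if prev_d is None else prev_d)
            if t > 0:
                prev_d = dhd[l][t - 1]
                dhd[l][t - 1] = (params[f"U{l}"].T @ da) + (0 if prev_d is None else prev_d)
    return loss


def loss_and_grads(
    params: dict[str, np.ndarray],
    widths: tuple[int, ...],
    samples: Sequence[SequenceSample],
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its gradients over a batch of sequences."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    total = 0.0
    for s in samples:
        probs, cache = _forward_sample(params, widths, s.x, dropout, rng)
        target = CLASS_CKD if s.label == 1 else CLASS_NOCKD
        total += _backward_sample(params, widths, cache, target, grads)
    n = len(samples)
    for k in grads:
        grads[k] /= n
    return total / n, grads


def forward(net: TrainedNet, sample: SequenceSample) -> float:
    """p(CKD) for one sequence (dropout inactive at inference)."""
    if sample.x.shape[1] != len(net.feature_spec.names):
        raise ValueError(
            f"sample has {sample.x.shape[1]} features, net expects "
            f"{len(net.feature_spec.names)}"
        )
    probs, _ = _forward_sample(net.params, net.config.hidden_layers, sample.x)
    return float(probs[CLASS_CKD])


def predict_proba(net: TrainedNet, samples: Sequence[SequenceSample]) -> np.ndarray:
    return np.array([forward(net, s) for s in samples])


def train(
    config: NetConfig,
    spec: FeatureSpec,
    samples: Sequence[SequenceSample],
) -> TrainedNet:
    """Train by BPTT with RMSprop; deterministic given ``config.seed``."""
    labels = {s.label for s in samples}
    if labels != {0, 1}:
        raise TrainingError(f"need samples of both classes, got labels {sorted(labels)}")
    n_features = len(spec.names)
    rng = np.random.default_rng(config.seed)
    params = init_params(config, n_features, rng)
    cache = {k: np.zeros_like(v) for k, v in params.items()}
    eps = 1e-8
    trace: list[float] = []
    idx = np.arange(len(samples))
    for _ in range(config.epochs):
        rng.shuffle(idx)
        epoch_losses = []
        for start in range(0, len(idx), config.batch_size):
            batch = [samples[i] for i in idx[start : start + config.batch_size]]
            loss, grads = loss_and_grads(
                params, config.hidden_layers, batch, config.dropout, rng
            )
            epoch_losses.append(loss)
            for k, g in grads.items():
                cache[k] = config.rmsprop_decay * cache[k] + (1 - config.rmsprop_decay) * g**2
                params[k] -= config.learning_rate * g / (np.sqrt(cache[k]) + eps)
        trace.append(float(np.mean(epoch_losses)))
    return TrainedNet(params=params, feature_spec=spec, config=config, loss_trace=trace)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _f1(labels: np.ndarray, probs: np.ndarray, cutoff: float = 0.5) -> float:
    pred = probs >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return (2 * tp / denom) if denom else 0.0


def cross_validated_f1(
    config: NetConfig,
    samples: Sequence[SequenceSample],
    folds: int = 3,
    spec: FeatureSpec | None = None,
) -> float:
    """Mean F1 (CKD positive, p=0.5 cutoff) over stratified CV folds.

    Models are trained with the cross-entropy loss; F1 is the fold score —
    this is the package's reading of scoring "F1 cross-entropy".
    """
    labels = np.array([s.label for s in samples])
    counts = np.bincount(labels, minlength=2)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds the smaller class count {counts.min()}")
    spec = spec or FeatureSpec(
        names=tuple(f"f{i}" for i in range(samples[0].x.shape[1])),
        scaler={},
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    scores = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), labels)):
        fold_cfg = replace(config, seed=config.seed + fold)
        net = train(fold_cfg, spec, [samples[i] for i in tr])
        probs = predict_proba(net, [samples[i] for i in te])
        scores.append(_f1(labels[te], probs))
    return float(np.mean(scores))


def wrapper_feature_selection(
    candidates: Sequence[str],
    build_samples: Callable[[Sequence[str]], list[SequenceSample]],
    folds: int = 3,
    base_config: NetConfig | None = None,
) -> dict[str, list[tuple[tuple[str, ...], float]]]:
    """Greedy bottom-up (forward) and top-down (backward) wrapper selection.

    ``build_samples(names)`` must return sequence samples restricted to (and
    standardised for) the given feature subset.  Returns, for each direction,
    the best subset at each size with its cross-validated F1.  The forward
    trace is nested by construction (size-k subset is contained in size-k+1).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    base_config = base_config or NetConfig(hidden_layers=(3, 7), epochs=4, dropout=0.0)

    def score(names: Sequence[str]) -> float:
        return cross_validated_f1(base_config, build_samples(names), folds)

    forward_trace: list[tuple[tuple[str, ...], float]] = []
    selected: list[str] = []
    remaining = list(candidates)
    while remaining:
        scored = [(score(selected + [f]), f) for f in remaining]
        best_score, best_f = max(scored, key=lambda t: t[0])
        selected.append(best_f)
        remaining.remove(best_f)
        forward_trace.append((tuple(selected), best_score))

    backward_trace: list[tuple[tuple[str, ...], float]] = []
    current = list(candidates)
    backward_trace.append((tuple(current), score(current)))
    while len(current) > 1:
        scored = [(score([f for f in current if f != drop]), drop) for drop in current]
        best_score, best_drop = max(scored, key=lambda t: t[0])
        current.remove(best_drop)
        backward_trace.append((tuple(current), best_score))

    return {"forward": forward_trace, "backward": backward_trace}


def count_params(config: NetConfig, n_features: int) -> int:
    n = 0
    fan_in = n_features
    for w in config.hidden_layers:
        n += w * fan_in + w * w + w
        fan_in = w
    return n + 2 * config.hidden_layers[-1] + 2


def architecture_screen(
    grid: Sequence[NetConfig],
    samples: Sequence[SequenceSample],
    folds: int = 10,
    n_features: int | None = None,
):
    """Score every configuration by mean CV F1; ties favour fewer parameters.

    Returns ``(best_config, table)`` where the table lists layer structure,
    parameter count and mean F1 per configuration.
    """
    import pandas as pd

    if not grid:
        raise ValueError("empty architecture grid")
    n_features = n_features or samples[0].x.shape[1]
    rows = []
    for cfg in grid:
        f1 = cross_validated_f1(cfg, samples, folds)
        rows.append(
            {
                "hidden_layers": "-".join(map(str, cfg.hidden_layers)),
                "n_params": count_params(cfg, n_features),
                "mean_cv_f1": f1,
                "config": cfg,
            }
        )
    best_row = max(rows, key=lambda r: (r["mean_cv_f1"], -r["n_params"]))
    table = pd.DataFrame([{k: r[k] for k in ("hidden_layers", "n_params", "mean_cv_f1")} for r in rows])
    return best_row["config"], table


# ---------------------------------------------------------------------------
# Persistence (JSON: weights + scaler + config + format version)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_net(net: TrainedNet, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "format_version": _FORMAT_VERSION,
        "params": {k: v.tolist() for k, v in net.params.items()},
        "feature_spec": {
            "names": list(net.feature_spec.names),
            "scaler": {k: list(v) for k, v in net.feature_spec.scaler.items()},
            "weight_fallback": net.feature_spec.weight_fallback,
        },
        "config": {
            "hidden_layers": list(net.config.hidden_layers),
            "dropout": net.config.dropout,
            "epochs": net.config.epochs,
            "learning_rate": net.config.learning_rate,
            "rmsprop_decay": net.config.rmsprop_decay,
            "batch_size": net.config.batch_size,
            "seed": net.config.seed,
        },
        "loss_trace": net.loss_trace,
    }
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path


def load_net(path: str | Path) -> TrainedNet:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
    spec = FeatureSpec(
        names=tuple(payload["feature_spec"]["names"]),
        scaler={k: tuple(v) for k, v in payload["feature_spec"]["scaler"].items()},
        weight_fallback=payload["feature_spec"]["weight_fallback"],
    )
    config = NetConfig(**{**payload["config"], "hidden_layers": tuple(payload["config"]["hidden_layers"])})
    params = {k: np.array(v, dtype=float) for k, v in payload["params"].items()}
    return TrainedNet(params=params, feature_spec=spec, config=config, loss_trace=payload["loss_trace"])
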