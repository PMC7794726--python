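"""Declarative CNN specifications, parameter accounting, training and inference.

Three canonical architectures are provided:

* ``context_cnn_spec`` — single-output 1-D CNN for rest/activity context
  (also used, identically, as a stand-alone tremor detector on raw windows);
* ``multitask_raw_spec`` — shared conv trunk on the raw 128x3 window with
  two dense branches (context head, tremor head);
* ``multitask_fft_spec`` — the same multitask layout adapted to the 64-bin
  one-sided spectrum of the Euclidean-norm signal (input 64x1).

``count_trainable_parameters`` evaluates the closed-form weight+bias count
from the spec alone; ``build_network`` instantiates the matching NumPy
network, so spec arithmetic and actual array sizes can be cross-checked.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "LayerSpec", "ModelSpec", "TrainConfig", "TrainedModel",
    "conv1d", "maxpool", "global_average_pool", "dense", "dropout", "head",
    "context_cnn_spec", "multitask_raw_spec", "multitask_fft_spec",
    "count_trainable_parameters", "build_network", "train", "predict_proba",
    "DegenerateLabelsError",
]


class DegenerateLabelsError(ValueError):
    """A classification head saw only one class in its training data."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    params: tuple = ()


def conv1d(filters: int, kernel: int = 8) -> LayerSpec:
    return LayerSpec("conv1d", (filters, kernel))


def maxpool(size: int = 2) -> LayerSpec:
    return LayerSpec("maxpool", (size,))


def global_average_pool() -> LayerSpec:
    return LayerSpec("global_average_pool")


def dense(units: int) -> LayerSpec:
    return LayerSpec("dense", (units,))


def dropout(rate: float) -> LayerSpec:
    return LayerSpec("dropout", (rate,))


def head() -> LayerSpec:
    """Single sigmoid output unit."""
    return LayerSpec("head")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    input_shape: tuple  # (length, channels)
    trunk: tuple
    heads: dict  # head name -> tuple of LayerSpec ending in head()

    @property
    def head_names(self):
        return tuple(self.heads)

    def to_json(self) -> str:
        obj = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "trunk": [[l.kind, list(l.params)] for l in self.trunk],
            "heads": {k: [[l.kind, list(l.params)] for l in v] for k, v in self.heads.items()},
        }
        return json.dumps(obj, indent=2)


def context_cnn_spec() -> ModelSpec:
    """Single-output context CNN: conv128 -> pool -> conv96 -> GAP -> dense190 -> sigmoid."""
    return ModelSpec(
        name="context_cnn",
        input_shape=(128, 3),
        trunk=(conv1d(128, 8), maxpool(2), conv1d(96, 8), global_average_pool(),
               dense(190)),
        heads={"output": (head(),)},
    )


def multitask_raw_spec() -> ModelSpec:
    """Multitask CNN on raw triaxial windows: both conv layers 128 filters,
    two branches of dense(190)+dropout(0.2)+sigmoid."""
    branch = (dense(190), dropout(0.2), head())
    return ModelSpec(
        name="multitask_raw",
        input_shape=(128, 3),
        trunk=(conv1d(128, 8), maxpool(2), conv1d(128, 8), global_average_pool()),
        heads={"context": branch, "tremor": branch},
    )


def multitask_fft_spec() -> ModelSpec:
    """Multitask CNN on the 64-bin spectrum; the second conv layer has 96
    filters (the width consistent with the published parameter total)."""
    branch = (dense(190), dropout(0.2), head())
    return ModelSpec(
        name="multitask_fft",
        input_shape=(64, 1),
        trunk=(conv1d(128, 8), maxpool(2), conv1d(96, 8), global_average_pool()),
        heads={"context": branch, "tremor": branch},
    )


def _count_chain(layers, length: int, channels: int, flat: int | None):
    """Walk a layer chain propagating (length, channels) or flat feature size."""
    total = 0
    for layer in layers:
        if layer.kind == "conv1d":
            filters, kernel = layer.params
            if flat is not None:
                raise ValueError("conv1d after flattening layer")
            total += channels * kernel * filters + filters
            channels = filters
        elif layer.kind == "maxpool":
            (size,) = layer.params
            length //= size
        elif layer.kind == "global_average_pool":
            flat = channels
        elif layer.kind == "dense":
            (units,) = layer.params
            if flat is None:
                raise ValueError("dense before flattening layer")
            total += flat * units + units
            flat = units
        elif layer.kind == "dropout":
            pass
        elif layer.kind == "head":
            if flat is None:
                raise ValueError("head before flattening layer")
            total += flat + 1
        else:
            raise ValueError(f"unknown layer kind: {layer.kind!r}")
    return total, length, channels, flat


def count_trainable_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter total (weights plus biases).

    Convolutions contribute in_channels*kernel*filters + filters, dense
    layers in*units + units, sigmoid heads in + 1; pooling and dropout are
    parameter-free. Padding does not affect the count.
    """
    length, channels = spec.input_shape
    total, length, channels, flat = _count_chain(spec.trunk, length, channels, None)
    for branch in spec.heads.values():
        btotal, _, _, _ = _count_chain(branch, length, channels, flat)
        total += btotal
    return int(total)


def _build_chain(layers, length, channels, flat, rng):
    built = []
    for layer in layers:
        if layer.kind == "conv1d":
            filters, kernel = layer.params
            built.append(nn.Conv1D(channels, filters, kernel, rng, activation="relu"))
            channels = filters
        elif layer.kind == "maxpool":
            built.append(nn.MaxPool1D(layer.params[0]))
            length //= layer.params[0]
        elif layer.kind == "global_average_pool":
            built.append(nn.GlobalAveragePool())
            flat = channels
        elif layer.kind == "dense":
            built.append(nn.Dense(flat, layer.params[0], rng, activation="relu"))
            flat = layer.params[0]
        elif layer.kind == "dropout":
            built.append(nn.Dropout(layer.params[0]))
        elif layer.kind == "head":
            built.append(nn.Dense(flat, 1, rng, activation="linear"))
        else:
            raise ValueError(f"unknown layer kind: {layer.kind!r}")
    return built, length, channels, flat


def build_network(spec: ModelSpec, rng: np.random.Generator) -> nn.Network:
    length, channels = spec.input_shape
    trunk, length, channels, flat = _build_chain(spec.trunk, length, channels, None, rng)
    branches = {}
    for name, branch_spec in spec.heads.items():
        branch, _, _, _ = _build_chain(branch_spec, length, channels, flat, rng)
        branches[name] = branch
    return nn.Network(trunk, branches)


@dataclass
class TrainConfig:
    learning_rate: float = 0.0046
    batch_size: int = 64
    max_epochs: int = 200
    early_stop_patience: int = 10
    validation_fraction: float = 0.2
    seed: int = 0
    monitor: str = "validation"  # or "test" to monitor held-out data directly

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainedModel:
    spec: ModelSpec
    weights: list
    history: dict
    best_epoch: int
    config: TrainConfig = field(default=None, repr=False)

    def network(self) -> nn.Network:
        net = build_network(self.spec, np.random.default_rng(0))
        net.set_weights(self.weights)
        return net

    def save(self, weights_path, spec_path=None) -> None:
        """Weights as .npz; JSON sidecar with the layer list and training setup."""
        np.savez(weights_path, **{f"p{i}": w for i, w in enumerate(self.weights)})
        if spec_path is not None:
            sidecar = {
                "spec": json.loads(self.spec.to_json()),
                "best_epoch": self.best_epoch,
                "config": asdict(self.config) if self.config else None,
                "n_parameters": int(sum(w.size for w in self.weights)),
            }
            with open(spec_path, "w") as fh:
                json.dump(sidecar, fh, indent=2)


def _as_label_arrays(spec, labels):
    if set(labels) != set(spec.head_names):
        raise ValueError(f"labels must provide heads {spec.head_names}, got {tuple(labels)}")
    return {k: np.asarray(v, dtype=float) for k, v in labels.items()}


def train(spec: ModelSpec, features: np.ndarray, labels: dict,
          config: TrainConfig, test_data=None) -> TrainedModel:
    """Train a network from ``spec`` on windows.

    Parameters
    ----------
    features : (n, length, channels) array matching ``spec.input_shape``.
    labels : mapping head name -> (n,) array of {0, 1}; entries of -1 are
        masked out of that head's loss (per-head invalid windows).
    config : optimisation settings. The early-stopping monitor is the loss
        on a held-out 20% validation split (or on ``test_data`` when
        ``config.monitor == "test"``), with weight restoration from the
        best epoch.
    test_data : optional (features, labels) pair, only used as the monitor
        when ``config.monitor == "test"``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.shape[1:] != tuple(spec.input_shape):
        raise ValueError(f"feature shape {x.shape[1:]} does not match spec input {spec.input_shape}")
    y = _as_label_arrays(spec, labels)
    n = len(x)
    if any(len(v) != n for v in y.values()):
        raise ValueError("features and labels are not aligned")

    rng = np.random.default_rng(config.seed)
    net = build_network(spec, rng)

    order = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("not enough samples to split off a validation set")

    for name, arr in y.items():
        seen = np.unique(arr[tr_idx][arr[tr_idx] >= 0])
        if len(seen) < 2:
            raise DegenerateLabelsError(f"head {name!r} has a single class in training data")

    if config.monitor == "test":
        if test_data is None:
            raise ValueError("monitor='test' requires test_data")
        mon_x = np.asarray(test_data[0], dtype=float)
        if mon_x.ndim == 2:
            mon_x = mon_x[:, :, None]
        mon_y = _as_label_arrays(spec, test_data[1])
    else:
        mon_x, mon_y = x[val_idx], {k: v[val_idx] for k, v in y.items()}

    opt = nn.Adam(net.params(), learning_rate=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_epoch, best_weights = np.inf, -1, net.get_weights()

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(tr_idx))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(tr_idx), config.batch_size):
            batch = tr_idx[perm[start:start + config.batch_size]]
            logits = net.forward(x[batch], train=True, rng=rng)
            loss, dlogits = 0.0, {}
            for name in spec.head_names:
                yb = y[name][batch]
                l, g = nn.bce_with_logits(logits[name], yb, yb >= 0)
                loss += l
                dlogits[name] = g
            net.backward(dlogits)
            opt.step(net.grads())
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))

        mon_logits = _forward_chunked(net, mon_x)
        mon_loss = 0.0
        for name in spec.head_names:
            ym = mon_y[name]
            l, _ = nn.bce_with_logits(mon_logits[name], ym, ym >= 0)
            mon_loss += l
        history["val_loss"].append(mon_loss)

        if mon_loss < best_loss:
            best_loss, best_epoch = mon_loss, epoch
            best_weights = net.get_weights()
        elif epoch - best_epoch >= config.early_stop_patience:
            break

    return TrainedModel(spec=spec, weights=best_weights, history=history,
                        best_epoch=best_epoch, config=config)


def _forward_chunked(net, x, batch_size=256):
    outs = None
    for start in range(0, len(x), batch_size):
        logits = net.forward(x[start:start + batch_size], train=False)
        if outs is None:
            outs = {k: [v] for k, v in logits.items()}
        else:
            for k, v in logits.items():
                outs[k].append(v)
    return {k: np.concatenate(v) for k, v in outs.items()}


def predict_proba(model: TrainedModel, features: np.ndarray) -> dict:
    """Per-head sigmoid probabilities for each window; dropout inactive."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.shape[1:] != tuple(model.spec.input_shape):
        raise ValueError(f"feature shape {x.shape[1:]} does not match spec input {model.spec.input_shape}")
    return model.network().predict(x)
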