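"""1D convolutional classifiers for start/stop windows, in pure numpy.

Four architectures (V1-V4) classify a raw ``(window_s * rate_hz) x 3``
acceleration slice as preceding/following true non-wear (1) or wear (0):

* V1 — one convolutional layer, one hidden dense layer;
* V2 — two convolutional layers (10 filters of kernel 15, then 50 filters
  of kernel 10 at the 100 Hz reference rate), one hidden dense layer of
  10 units;
* V3 — three convolutional layers with more filters per layer;
* V4 — V2 with a max-pooling layer after each convolutional layer.

All end in a single sigmoid output unit.  Training uses Adam (lr 0.001),
binary cross entropy, minibatches, and early stopping on validation loss
with a patience of 25 epochs and restoration of the best weights.  The
convolutions are ``valid`` with stride 1, so the data reaching the first
dense layer is a flattened slab whose size grows linearly with the input
length.

Everything is implemented directly on numpy arrays: the windows involved
are small (hundreds of rows, three channels), so explicit einsum-based
convolutions train these models in seconds on one CPU, and runs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .evaluation import ConfusionCounts, MetricSummary, compute_metrics
from .features import FeatureDataset, FeatureWindow

REFERENCE_RATE_HZ = 100.0

#: (filters, kernel size at 100 Hz) per convolutional layer, and hidden dense
#: units, per architecture.  V4 shares V2's convolutions with a pool after each.
ARCHITECTURES = {
    "V1": {"conv": [(10, 15)], "pool": [], "dense": [10]},
    "V2": {"conv": [(10, 15), (50, 10)], "pool": [], "dense": [10]},
    "V3": {"conv": [(20, 15), (100, 10), (100, 5)], "pool": [], "dense": [10]},
    "V4": {"conv": [(10, 15), (50, 10)], "pool": [2, 2], "dense": [10]},
}


class ModelConstructionError(ValueError):
    """Raised when layer hyperparameters are incompatible with the input length."""


@dataclass
class CnnConfig:
    architecture: str = "V2"
    window_s: float = 3
    rate_hz: float = 100.0
    conv_specs: list | None = None  # [(filters, kernel_size), ...] override
    pooling: list | None = None  # per-conv max-pool sizes override
    dense_units: list | None = None
    lr: float = 0.001
    max_epochs: int = 250
    patience: int = 25
    batch_size: int = 32
    seed: int = 0
    decision_threshold: float = 0.5
    center_input: bool = True  # parameter-free gravity-offset removal layer

    def layer_plan(self) -> tuple[list, list, list]:
        """Resolve conv/pool/dense specs, scaling kernels to the actual rate."""
        if self.architecture not in ARCHITECTURES:
            raise ModelConstructionError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(ARCHITECTURES)}"
            )
        arch = ARCHITECTURES[self.architecture]
        scale = self.rate_hz / REFERENCE_RATE_HZ
        # scale kernels with the rate (identity at 100 Hz) but keep each
        # receptive field at least ~0.5 s wide so the removal/attachment
        # oscillation stays visible to the convolutions at low rates
        floor = int(round(0.5 * self.rate_hz))
        conv = self.conv_specs or [
            (f, max(2, min(k, floor), int(round(k * scale)))) for f, k in arch["conv"]
        ]
        pool = self.pooling if self.pooling is not None else list(arch["pool"])
        dense = self.dense_units or list(arch["dense"])
        return list(conv), list(pool), list(dense)

    @property
    def input_shape(self) -> tuple[int, int]:
        return int(round(self.window_s * self.rate_hz)), 3


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def build(self, shape: tuple, rng: np.random.Generator) -> tuple:
        raise NotImplementedError

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ChannelCenter(_Layer):
    """Parameter-free per-window, per-axis mean removal.

    Within a few-second window the gravity component is an approximately
    constant per-axis offset set by device orientation; the removal /
    attachment signature lives entirely in the dynamics around it.  This
    fixed layer subtracts each channel's within-window mean so the
    convolutions see orientation-invariant input.  It has no trainable
    parameters, so the architecture's parameter counts are unaffected.
    """

    def __init__(self):
        self.params, self.grads = [], []

    def build(self, shape, rng):
        return shape

    def forward(self, x, train=False):
        return x - x.mean(axis=1, keepdims=True)

    def backward(self, dout):
        return dout - dout.mean(axis=1, keepdims=True)


class Conv1D(_Layer):
    """Valid, stride-1 1D convolution with ReLU activation."""

    def __init__(self, filters: int, kernel_size: int, name: str = "conv"):
        self.filters = filters
        self.kernel_size = kernel_size
        self.name = name
        self.params, self.grads = [], []

    def build(self, shape, rng):
        length, channels = shape
        if self.kernel_size > length:
            raise ModelConstructionError(
                f"layer {self.name}: kernel size {self.kernel_size} exceeds "
                f"input length {length}"
            )
        # He-style fan-in scaling suits the ReLU stack
        limit = np.sqrt(6.0 / (self.kernel_size * channels))
        w = rng.uniform(-limit, limit, size=(self.kernel_size, channels, self.filters))
        b = np.zeros(self.filters)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        return (length - self.kernel_size + 1, self.filters)

    def forward(self, x, train=False):
        w, b = self.params
        # windows: (B, L_out, C, K)
        windows = sliding_window_view(x, self.kernel_size, axis=1)
        z = np.einsum("blck,kcf->blf", windows, w) + b
        if train:
            self._windows, self._z = windows, z
        return np.maximum(z, 0.0)

    def backward(self, dout):
        w, _ = self.params
        dz = dout * (self._z > 0)
        self.grads[0][...] = np.einsum("blck,blf->kcf", self._windows, dz)
        self.grads[1][...] = dz.sum(axis=(0, 1))
        b_sz, l_out, _ = dz.shape
        dx = np.zeros((b_sz, l_out + self.kernel_size - 1, w.shape[1]))
        for k in range(self.kernel_size):
            dx[:, k : k + l_out, :] += np.einsum("blf,cf->blc", dz, w[k])
        return dx


class MaxPool1D(_Layer):
    """Non-overlapping max pooling along the time axis (remainder truncated)."""

    def __init__(self, size: int, name: str = "pool"):
        self.size = size
        self.name = name
        self.params, self.grads = [], []

    def build(self, shape, rng):
        length, channels = shape
        if length // self.size < 1:
            raise ModelConstructionError(
                f"layer {self.name}: pool size {self.size} leaves no output "
                f"for input length {length}"
            )
        return (length // self.size, channels)

    def forward(self, x, train=False):
        b_sz, length, channels = x.shape
        l_out = length // self.size
        blocks = x[:, : l_out * self.size, :].reshape(b_sz, l_out, self.size, channels)
        if train:
            self._argmax = blocks.argmax(axis=2)
            self._in_shape = x.shape
        return blocks.max(axis=2)

    def backward(self, dout):
        b_sz, l_out, channels = dout.shape
        dx = np.zeros(self._in_shape)
        bi, li, ci = np.ogrid[:b_sz, :l_out, :channels]
        dx[bi, li * self.size + self._argmax, ci] = dout
        return dx


class Flatten(_Layer):
    def __init__(self):
        self.params, self.grads = [], []

    def build(self, shape, rng):
        self._shape = shape
        return (int(np.prod(shape)),)

    def forward(self, x, train=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape((dout.shape[0], *self._shape))


class Dense(_Layer):
    """Fully connected layer; activation 'relu' or 'linear'."""

    def __init__(self, units: int, activation: str = "relu", name: str = "dense"):
        self.units = units
        self.activation = activation
        self.name = name
        self.params, self.grads = [], []

    def build(self, shape, rng):
        (n_in,) = shape
        limit = (
            np.sqrt(6.0 / n_in)  # He-style for the ReLU hidden layers
            if self.activation == "relu"
            else np.sqrt(6.0 / (n_in + self.units))
        )
        w = rng.uniform(-limit, limit, size=(n_in, self.units))
        b = np.zeros(self.units)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        return (self.units,)

    def forward(self, x, train=False):
        w, b = self.params
        z = x @ w + b
        if train:
            self._x, self._z = x, z
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout):
        w, _ = self.params
        dz = dout * (self._z > 0) if self.activation == "relu" else dout
        self.grads[0][...] = self._x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ w.T


# ---------------------------------------------------------------------------
# model


class Sequential:
    """A layer stack ending in a single sigmoid output unit.

    The final dense layer produces a logit; :meth:`predict_proba` applies the
    sigmoid.  Keeping the head in logit form lets training use the fused,
    numerically stable sigmoid + binary-cross-entropy gradient.
    """

    def __init__(self, layers: list[_Layer], input_shape: tuple[int, int], seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        if shape != (1,):
            raise ModelConstructionError(
                f"model must end in a single output unit, got shape {shape}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward_logits(np.asarray(x, dtype=float))
        return 1.0 / (1.0 + np.exp(-z))

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w


def build_model(cfg: CnnConfig) -> Sequential:
    """Instantiate the configured architecture for the configured input shape."""
    conv, pool, dense = cfg.layer_plan()
    layers: list[_Layer] = []
    if cfg.center_input:
        layers.append(ChannelCenter())
    for i, (filters, kernel) in enumerate(conv):
        layers.append(Conv1D(filters, kernel, name=f"conv{i + 1}"))
        if i < len(pool):
            layers.append(MaxPool1D(pool[i], name=f"pool{i + 1}"))
    layers.append(Flatten())
    for i, units in enumerate(dense):
        layers.append(Dense(units, activation="relu", name=f"dense{i + 1}"))
    layers.append(Dense(1, activation="linear", name="output"))
    return Sequential(layers, input_shape=cfg.input_shape, seed=cfg.seed)


def count_parameters(model: Sequential) -> int:
    """Total trainable weights + biases of a built model."""
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-indexed
    stopped_epoch: int = 0


class _Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FeatureDataset):
        return data.as_arrays()
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _bce_and_accuracy(model: Sequential, x, y) -> tuple[float, float]:
    z = model.forward_logits(x)
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    acc = float(np.mean((z >= 0.0) == (y >= 0.5)))
    return loss, acc


def train_model(
    model: Sequential, train_set, val_set, cfg: CnnConfig
) -> tuple[Sequential, TrainingHistory]:
    """Train with Adam + binary cross entropy and early stopping.

    Stops when the validation loss has not improved for ``cfg.patience``
    epochs (or at ``cfg.max_epochs``) and restores the weights of the epoch
    with the lowest validation loss.  Deterministic for a fixed ``cfg.seed``.
    """
    x_train, y_train = _as_xy(train_set)
    x_val, y_val = _as_xy(val_set)
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng([cfg.seed, 1])
    opt = _Adam(model.parameters(), lr=cfg.lr)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    n = x_train.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            z = model.forward_logits(xb, train=True)
            prob = 1.0 / (1.0 + np.exp(-z))
            model.backward((prob - yb) / xb.shape[0])
            opt.step(model.gradients())
        tr_loss, tr_acc = _bce_and_accuracy(model, x_train, y_train)
        va_loss, va_acc = _bce_and_accuracy(model, x_val, y_val)
        history.train_loss.append(tr_loss)
        history.val_loss.append(va_loss)
        history.train_accuracy.append(tr_acc)
        history.val_accuracy.append(va_acc)
        if va_loss < best_val:
            best_val = va_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        history.stopped_epoch = epoch
        if epochs_since_best >= cfg.patience:
            break
    model.set_weights(best_weights)
    return model, history


def train_with_restarts(
    cfg: CnnConfig, train_set, val_set, n_restarts: int = 3
) -> tuple[Sequential, TrainingHistory]:
    """Train ``n_restarts`` freshly initialised models; keep the best.

    Model selection is by lowest validation loss at each run's best epoch —
    the test split is never consulted.  With a few hundred training windows,
    a single run of a 10^5-parameter network occasionally settles on a poor
    plateau before patience fires; a handful of seeded restarts makes the
    procedure robust.  Restart ``r`` derives its weight-init and shuffling
    seed from ``(cfg.seed, r)``, so the whole procedure is deterministic.
    """
    best: tuple[Sequential, TrainingHistory] | None = None
    best_loss = np.inf
    for r in range(n_restarts):
        sub = int(np.random.default_rng([cfg.seed, r]).integers(2**31))
        run_cfg = replace_cfg(cfg, seed=sub)
        model = build_model(run_cfg)
        model, history = train_model(model, train_set, val_set, run_cfg)
        run_loss = history.val_loss[history.best_epoch - 1]
        if run_loss < best_loss:
            best_loss = run_loss
            best = (model, history)
    assert best is not None
    return best


def replace_cfg(cfg: CnnConfig, **kwargs) -> CnnConfig:
    from dataclasses import replace

    return replace(cfg, **kwargs)


def predict(
    model: Sequential,
    windows: Sequence[FeatureWindow] | np.ndarray,
    threshold: float = 0.5,
) -> list[tuple[float, int]]:
    """Per-window (probability, class); class 1 iff probability >= threshold."""
    if len(windows) == 0:
        return []
    if isinstance(windows[0], FeatureWindow):
        x = np.stack([w.matrix for w in windows])
    else:
        x = np.asarray(windows, dtype=float)
    probs = model.predict_proba(x)
    return [(float(p), int(p >= threshold)) for p in probs]


def evaluate_on_split(model: Sequential, test_set) -> MetricSummary:
    """Window-level accuracy/precision/recall/F1 on a labelled set."""
    x, y = _as_xy(test_set)
    preds = np.array([c for _, c in predict(model, x)])
    y = y.astype(int)
    return compute_metrics(
        ConfusionCounts(
            tp=int(np.sum((preds == 1) & (y == 1))),
            fp=int(np.sum((preds == 1) & (y == 0))),
            fn=int(np.sum((preds == 0) & (y == 1))),
            tn=int(np.sum((preds == 0) & (y == 0))),
        )
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: Sequential, cfg: CnnConfig, weights_path, config_path) -> None:
    arrays = {f"w{i:03d}": w for i, w in enumerate(model.get_weights())}
    np.savez(weights_path, **arrays)
    Path(config_path).write_text(json.dumps(asdict(cfg), indent=2) + "\n")


def load_model(weights_path, config_path) -> tuple[Sequential, CnnConfig]:
    cfg = CnnConfig(**json.loads(Path(config_path).read_text()))
    model = build_model(cfg)
    with np.load(weights_path) as data:
        model.set_weights([data[k] for k in sorted(data.files)])
    return model, cfg
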