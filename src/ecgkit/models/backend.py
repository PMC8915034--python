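"""NumPy training backend for the 1-D CNN architecture specs.

Forward and backward passes are expressed as im2col + matrix products
so the heavy lifting runs in BLAS; arithmetic is float32. Training uses
mini-batch Adam on binary cross-entropy with inverted dropout. All
randomness (weight init, shuffling, dropout masks) flows from a single
integer seed, so runs are bit-reproducible on a fixed BLAS build.

The backend's parameter total is compared with the analytic count at
build time; a mismatch is a transcription bug and raises immediately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ecgkit.models.architectures import (
    ArchitectureSpec,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    count_trainable_parameters,
)
from ecgkit.preprocess import Dataset

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are six epochs of batch-32 Adam."""

    epochs: int = 6
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "binary_cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "binary_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(B, N, D) -> (B, N-K+1, K*D) patch matrix (copies into C order)."""
    b, _, d = x.shape
    v = sliding_window_view(x, kernel, axis=1)  # (B, L, D, K)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(b, -1, kernel * d)


class _ConvLayer:
    def __init__(self, spec: Conv1D, in_channels: int, rng: np.random.Generator):
        fan_in = spec.kernel * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
        self.w = rng.normal(0.0, scale, size=(fan_in, spec.filters)).astype(np.float32)
        self.b = np.zeros(spec.filters, dtype=np.float32)
        self.kernel = spec.kernel
        self.in_channels = in_channels

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, n, _ = x.shape
        col = _im2col(x, self.kernel)  # (B, L, K*D)
        l = col.shape[1]
        self._col2 = col.reshape(b * l, -1)
        self._in_len = n
        y = self._col2 @ self.w  # (B*L, F)
        y += self.b
        self._mask = y > 0
        np.multiply(y, self._mask, out=y)
        return y.reshape(b, l, -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        b, l, f = dy.shape
        dy2 = dy.reshape(b * l, f)
        np.multiply(dy2, self._mask, out=dy2)
        dw = self._col2.T @ dy2
        db = dy2.sum(axis=0)
        dx = None
        if need_dx:
            # col2im as one GEMM per kernel tap: keeps reads and the
            # strided accumulation into dx cache-friendly
            d = self.in_channels
            wk = self.w.reshape(self.kernel, d, f)
            dx = np.zeros((b, self._in_len, d), dtype=np.float32)
            for k in range(self.kernel):
                dx[:, k : k + l, :] += (dy2 @ wk[k].T).reshape(b, l, d)
        self._col2 = self._mask = None
        return dx, [dw, db]


class _PoolLayer:
    def __init__(self, spec: MaxPool1D):
        if spec.pool != 2 or spec.stride != 2:
            raise ValueError("only pool=2 stride=2 is supported")

    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_len = x.shape[1]
        n2 = self._in_len // 2
        a = x[:, 0 : 2 * n2 : 2, :]
        c = x[:, 1 : 2 * n2 : 2, :]
        self._left = a >= c  # ties take the earlier sample
        return np.where(self._left, a, c)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        b, n2, d = dy.shape
        dx = np.zeros((b, self._in_len, d), dtype=np.float32)
        np.multiply(dy, self._left, out=dx[:, 0 : 2 * n2 : 2, :])
        np.multiply(dy, np.logical_not(self._left), out=dx[:, 1 : 2 * n2 : 2, :])
        self._left = None
        return dx, []


class _DropoutLayer:
    def __init__(self, spec: Dropout, rng: np.random.Generator):
        self.rate = spec.rate
        # fast dedicated bit generator; masks dominate RNG cost
        self.rng = np.random.Generator(np.random.SFC64(rng.integers(2**63)))

    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training:
            self._mask = None
            return x
        # in-place on x: safe because the preceding conv layer keeps no
        # reference to its output, only to its input patches and mask
        self._scale = np.float32(1.0 / (1.0 - self.rate))
        self._mask = self.rng.random(x.shape, dtype=np.float32) >= self.rate
        np.multiply(x, self._mask, out=x)
        x *= self._scale
        return x

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        if self._mask is None:
            return dy, []
        np.multiply(dy, self._mask, out=dy)
        dy *= self._scale
        self._mask = None
        return dy, []


class _FlattenLayer:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        return dy.reshape(self._shape), []


class _DenseLayer:
    def __init__(self, spec: Dense, fan_in: int, rng: np.random.Generator):
        if spec.activation == "relu":
            scale = np.sqrt(2.0 / fan_in)
        else:  # Glorot for the sigmoid head
            scale = np.sqrt(1.0 / fan_in)
        self.w = rng.normal(0.0, scale, size=(fan_in, spec.units)).astype(np.float32)
        self.b = np.zeros(spec.units, dtype=np.float32)
        self.activation = spec.activation

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, np.float32(0.0))
        np.clip(z, -60.0, 60.0, out=z)  # avoid float32 exp overflow
        out = 1.0 / (1.0 + np.exp(-z, dtype=np.float32))
        self._out = out
        return out

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        # For the sigmoid head, the trainer passes d(loss)/d(logit)
        # directly, so no activation derivative is applied here.
        if self.activation == "relu":
            dy = np.where(self._mask, dy, np.float32(0.0))
        dw = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.w.T if need_dx else None
        self._x = None
        return dx, [dw, db]


class NumpyCnn:
    """A sequential 1-D CNN instantiated from an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = []
        length, channels = spec.input_length, spec.input_channels
        flat = False
        for layer in spec.layers:
            if isinstance(layer, Conv1D):
                self.layers.append(_ConvLayer(layer, channels, rng))
                length, channels = length - layer.kernel + 1, layer.filters
            elif isinstance(layer, MaxPool1D):
                self.layers.append(_PoolLayer(layer))
                length //= 2
            elif isinstance(layer, Dropout):
                self.layers.append(_DropoutLayer(layer, rng))
            elif isinstance(layer, Flatten):
                self.layers.append(_FlattenLayer())
                length, channels, flat = length * channels, 1, True
            elif isinstance(layer, Dense):
                self.layers.append(_DenseLayer(layer, length, rng))
                length = layer.units
            else:  # pragma: no cover
                raise TypeError(f"unknown layer spec {layer!r}")
        self._rng = rng

    @property
    def n_parameters(self) -> int:
        """Backend parameter total (sizes of all weight/bias arrays)."""
        return sum(int(p.size) for layer in self.layers for p in layer.params)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 2:
            out = out[:, :, None]
        if out.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected segments of length {self.spec.input_length}, "
                f"got {out.shape[1]}"
            )
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]

    def predict_scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid probabilities in [0, 1], computed without dropout."""
        x = np.asarray(x, dtype=np.float32)
        scores = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(scores) if scores else np.empty(0, dtype=np.float32)

    def _train_step(self, xb: np.ndarray, yb: np.ndarray, adam_state, config) -> tuple[float, float]:
        p = self.forward(xb, training=True)
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        loss = float(-np.mean(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc)))
        acc = float(np.mean((p >= 0.5) == (yb >= 0.5)))
        # d(loss)/d(logit) for sigmoid + BCE
        grad = ((p - yb) / np.float32(len(yb)))[:, None]
        grads: list[np.ndarray] = []
        dy: np.ndarray = grad
        for i in reversed(range(len(self.layers))):
            dy, layer_grads = self.layers[i].backward(dy, need_dx=(i > 0))
            grads = layer_grads + grads
        self._adam_update(grads, adam_state, config)
        return loss, acc

    def _adam_update(self, grads, state, config) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        state["t"] += 1
        t = state["t"]
        lr = config.learning_rate * np.sqrt(1.0 - beta2**t) / (1.0 - beta1**t)
        params = [p for layer in self.layers for p in layer.params]
        for p, g, m, v in zip(params, grads, state["m"], state["v"]):
            m *= beta1
            m += (1.0 - beta1) * g
            v *= beta2
            v += (1.0 - beta2) * np.square(g)
            p -= (lr * m / (np.sqrt(v) + eps)).astype(np.float32)

    def fit(self, x: np.ndarray, y: np.ndarray, config: TrainConfig) -> list[dict[str, float]]:
        """Mini-batch Adam training; returns per-epoch mean loss/accuracy."""
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if len(x) == 0:
            raise ValueError("training set is empty")
        params = [p for layer in self.layers for p in layer.params]
        state = {
            "t": 0,
            "m": [np.zeros_like(p) for p in params],
            "v": [np.zeros_like(p) for p in params],
        }
        shuffle_rng = np.random.default_rng(config.seed)
        history = []
        for _ in range(config.epochs):
            order = shuffle_rng.permutation(len(x))
            losses, accs = [], []
            for start in range(0, len(x), config.batch_size):
                idx = order[start : start + config.batch_size]
                loss, acc = self._train_step(x[idx], y[idx], state, config)
                losses.append(loss)
                accs.append(acc)
            history.append(
                {"loss": float(np.mean(losses)), "accuracy": float(np.mean(accs))}
            )
        return history

    def forward_multiply_count(self, batch: int = 1) -> int:
        """Multiply count of one forward pass, measured from actual
        matmul operand shapes (per example)."""
        x = np.zeros((batch, self.spec.input_length, self.spec.input_channels), np.float32)
        total = 0
        out = x
        for layer in self.layers:
            if isinstance(layer, _ConvLayer):
                col = _im2col(out, layer.kernel)
                total += col.shape[1] * col.shape[2] * layer.w.shape[1]
            elif isinstance(layer, _DenseLayer):
                total += layer.w.shape[0] * layer.w.shape[1]
            out = layer.forward(out, training=False)
        return total


def build_model(spec: ArchitectureSpec, seed: int = 0) -> NumpyCnn:
    """Instantiate a network and verify its parameter total analytically.

    Raises
    ------
    RuntimeError
        If the backend's parameter total disagrees with the analytic
        count (an architecture transcription bug).
    """
    model = NumpyCnn(spec, seed=seed)
    analytic = count_trainable_parameters(spec)
    if model.n_parameters != analytic:
        raise RuntimeError(
            f"backend parameter total {model.n_parameters} != analytic "
            f"count {analytic} for {spec.name}"
        )
    return model


def build_and_train(
    spec: ArchitectureSpec, dataset: Dataset, config: TrainConfig
) -> tuple[NumpyCnn, list[dict[str, float]]]:
    """Build a network from ``spec`` and train it on the dataset's train split."""
    x, y = dataset.arrays("train")
    if len(x) == 0:
        raise ValueError("dataset has no training segments")
    if np.unique(y).size < 2:
        raise ValueError("training split must contain both classes")
    model = build_model(spec, seed=config.seed)
    history = model.fit(x, y, config)
    return model, history


def predict_scores(model: NumpyCnn, segments: np.ndarray) -> np.ndarray:
    """Per-segment sigmoid probabilities; thresholding at 0.5 gives labels."""
    return model.predict_scores(np.asarray(segments))
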