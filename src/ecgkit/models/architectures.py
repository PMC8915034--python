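"""Backend-independent 1-D CNN layer specs and analytic bookkeeping.

Shape propagation follows the valid-convolution / floor-pooling
convention: a Conv1D with kernel K maps length N to N - K + 1, a
MaxPool1D with pool 2 stride 2 maps N to floor(N / 2). Trainable
parameters: a Conv1D over D input channels with L filters of kernel K
contributes (K*D + 1)*L; a Dense layer contributes (fan_in + 1)*units;
pooling, dropout and flatten contribute none. Per-conv multiply cost is
K*D*L per output position, i.e. Theta(K*N*D*L) per example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union


@dataclass(frozen=True)
class Conv1D:
    filters: int
    kernel: int
    activation: str = "relu"
    padding: str = "valid"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.filters < 1:
            raise ValueError("kernel and filters must be >= 1")
        if self.padding != "valid":
            raise ValueError("only valid (unpadded) convolution is supported")


@dataclass(frozen=True)
class MaxPool1D:
    pool: int = 2
    stride: int = 2


@dataclass(frozen=True)
class Dropout:
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rate < 1.0:
            raise ValueError(f"dropout rate must be in (0, 1), got {self.rate}")


@dataclass(frozen=True)
class Flatten:
    pass


@dataclass(frozen=True)
class Dense:
    units: int
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"unsupported activation {self.activation!r}")


LayerSpec = Union[Conv1D, MaxPool1D, Dropout, Flatten, Dense]


@dataclass(frozen=True)
class ArchitectureSpec:
    """An ordered layer stack on a fixed-length single-channel input.

    Must contain exactly one Flatten before the first Dense layer and
    end in a single sigmoid unit (binary classification head).
    """

    name: str
    layers: tuple[LayerSpec, ...]
    input_length: int = 2160
    input_channels: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("architecture must have at least one layer")
        last = self.layers[-1]
        if not (isinstance(last, Dense) and last.units == 1 and last.activation == "sigmoid"):
            raise ValueError("architecture must end in Dense(1, sigmoid)")
        first_dense = next(
            (i for i, l in enumerate(self.layers) if isinstance(l, Dense)), None
        )
        flatten_idx = [i for i, l in enumerate(self.layers) if isinstance(l, Flatten)]
        if len(flatten_idx) != 1 or flatten_idx[0] > first_dense:
            raise ValueError("exactly one Flatten must precede the first Dense layer")
        propagate_shapes(self)  # raises on non-positive intermediate lengths


def _conv_block(filters: int, kernel: int, dropout: float) -> tuple[LayerSpec, ...]:
    return (Conv1D(filters, kernel), Dropout(dropout), MaxPool1D())


def model1_spec() -> ArchitectureSpec:
    """Model-1: five conv blocks, dropout 0.5 x3 then 0.25 x2, sigmoid head."""
    layers: list[LayerSpec] = []
    for (f, k), rate in zip(
        [(400, 20), (256, 15), (178, 7), (88, 5), (44, 3)],
        [0.5, 0.5, 0.5, 0.25, 0.25],
    ):
        layers.extend(_conv_block(f, k, rate))
    layers += [Flatten(), Dense(1, "sigmoid")]
    return ArchitectureSpec("model1", tuple(layers))


def model2_spec() -> ArchitectureSpec:
    """Model-2: five conv blocks (kernels 20/15/10/7/20), dropout 0.25, sigmoid head.

    The third convolution uses 256 filters; this is the width consistent
    with the architecture's 5,274,443-parameter total.
    """
    layers: list[LayerSpec] = []
    for f, k in [(600, 20), (400, 15), (256, 10), (178, 7), (88, 20)]:
        layers.extend(_conv_block(f, k, 0.25))
    layers += [Flatten(), Dense(1, "sigmoid")]
    return ArchitectureSpec("model2", tuple(layers))


def model3_spec() -> ArchitectureSpec:
    """Model-3: four conv blocks (kernel 5), dropout 0.5, dense head 50-32-1."""
    layers: list[LayerSpec] = []
    for f in [256, 128, 72, 36]:
        layers.extend(_conv_block(f, 5, 0.5))
    layers += [Flatten(), Dense(50, "relu"), Dense(32, "relu"), Dense(1, "sigmoid")]
    return ArchitectureSpec("model3", tuple(layers))


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """Per-layer output shapes as (length, channels); flat layers use (units, 1).

    Raises if any layer would see a non-positive length, naming it.
    """
    length, channels = spec.input_length, spec.input_channels
    flat = False
    shapes: list[tuple[int, int]] = []
    for i, layer in enumerate(spec.layers):
        label = f"layer {i} ({type(layer).__name__})"
        if isinstance(layer, Conv1D):
            length = length - layer.kernel + 1
            channels = layer.filters
            if length <= 0:
                raise ValueError(f"{label}: non-positive output length {length}")
        elif isinstance(layer, MaxPool1D):
            length = length // layer.stride
            if length <= 0:
                raise ValueError(f"{label}: non-positive output length {length}")
        elif isinstance(layer, Flatten):
            length, channels, flat = length * channels, 1, True
        elif isinstance(layer, Dense):
            if not flat:
                raise ValueError(f"{label}: Dense before Flatten")
            length = layer.units
        shapes.append((length, channels))
    return shapes


def flatten_length(spec: ArchitectureSpec) -> int:
    """Fan-in of the first Dense layer (length x channels at the Flatten)."""
    shapes = propagate_shapes(spec)
    for layer, shape in zip(spec.layers, shapes):
        if isinstance(layer, Flatten):
            return shape[0]
    raise ValueError("architecture has no Flatten layer")


def count_trainable_parameters(spec: ArchitectureSpec) -> int:
    """Analytic trainable-parameter total (weights + biases), no backend."""
    length, channels = spec.input_length, spec.input_channels
    total = 0
    for layer, (out_len, out_ch) in zip(spec.layers, propagate_shapes(spec)):
        if isinstance(layer, Conv1D):
            total += (layer.kernel * channels + 1) * layer.filters
        elif isinstance(layer, Dense):
            total += (length + 1) * layer.units
        length, channels = out_len, out_ch
    return total


def conv_cost_profile(spec: ArchitectureSpec) -> list[dict[str, int]]:
    """Multiply counts per convolution layer for one example.

    Each entry reports the layer's K (kernel), N (input length), D
    (input channels), L (filters), its exact multiply count
    K*(N-K+1)*D*L, and the K*N*D*L upper bound that gives the
    architecture's O(K*N*D*L) per-layer time complexity.
    """
    profile = []
    length, channels = spec.input_length, spec.input_channels
    for i, (layer, (out_len, out_ch)) in enumerate(zip(spec.layers, propagate_shapes(spec))):
        if isinstance(layer, Conv1D):
            exact = layer.kernel * out_len * channels * layer.filters
            profile.append(
                {
                    "layer": i,
                    "K": layer.kernel,
                    "N": length,
                    "D": channels,
                    "L": layer.filters,
                    "multiplies": exact,
                    "bound_KNDL": layer.kernel * length * channels * layer.filters,
                }
            )
        length, channels = out_len, out_ch
    return profile
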