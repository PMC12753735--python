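"""Model containers and declarative architecture summaries.

A :class:`ModelSpec` is the declarative description of a network — one row
per layer with output shape, kernel, activation and the closed-form
trainable-parameter count — mirroring the summary tables that frameworks
print.  It is computed by pure arithmetic, independently of the weight
arrays, so it can audit the runtime model (``Sequential.count_params``)
against the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Layer


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str  # conv | pool | upsample | concat | dense | dropout | flatten | input
    output_shape: tuple  # (H, W, C) or (units,) — batch dim omitted
    n_params: int
    kernel: tuple | None = None
    activation: str | None = None

    def __post_init__(self):
        if self.kind in ("pool", "upsample", "concat", "dropout", "flatten", "input"):
            if self.n_params != 0:
                raise ValueError(f"{self.kind} layer {self.name} must have 0 parameters")


@dataclass
class ModelSpec:
    layers: list[LayerSpec] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def row(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


def count_trainable_params(spec: ModelSpec) -> int:
    """Sum of per-layer closed-form parameter counts (weight-value free)."""
    return spec.total_params


def conv_params(kernel: int, c_in: int, c_out: int) -> int:
    """kh*kw*c_in*c_out weights + c_out biases."""
    return kernel * kernel * c_in * c_out + c_out


def dense_params(n_in: int, n_out: int) -> int:
    return n_in * n_out + n_out


class Sequential:
    """Plain layer chain (used by the cell classifier)."""

    def __init__(self, layers: list[Layer], spec: ModelSpec | None = None):
        self.layers = layers
        self.spec = spec

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def trainable(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    def count_params(self) -> int:
        return int(sum(l.param_count() for l in self.layers))

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.trainable():
            out.extend(np.copy(p) for p in l.params.values())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.trainable():
            for key in l.params:
                l.params[key][...] = next(it)
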