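"""Trainable layers (NHWC, float32, stride 1 / pool 2 only)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gelu(z: np.ndarray) -> np.ndarray:
    # tanh approximation
    c = np.sqrt(2.0 / np.pi).astype(np.float32)
    return 0.5 * z * (1.0 + np.tanh(c * (z + 0.044715 * z**3)))


def _gelu_grad(z: np.ndarray) -> np.ndarray:
    c = np.sqrt(2.0 / np.pi)
    t = np.tanh(c * (z + 0.044715 * z**3))
    return 0.5 * (1.0 + t) + 0.5 * z * (1.0 - t**2) * c * (1.0 + 3 * 0.044715 * z**2)


class Layer:
    """Base layer.  Subclasses cache what backward needs during forward."""

    name: str = ""

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """2-D convolution, stride 1, 'same' or 'valid' padding.

    ``fused_head=True`` marks the network head whose activation derivative
    is folded into the loss gradient: ``backward`` then expects
    d(loss)/d(logits) rather than d(loss)/d(activation).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        padding: str = "same",
        activation: str | None = "relu",
        l2: float = 0.0,
        name: str = "conv",
        rng: np.random.Generator | None = None,
        fused_head: bool = False,
    ):
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * c_in
        # He-normal initialisation
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (kernel, kernel, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self.padding = padding
        self.activation = activation
        self.l2 = float(l2)
        self.name = name
        self.fused_head = fused_head
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.dW, "b": self.db}

    def _pad(self) -> int:
        return (self.kernel - 1) // 2 if self.padding == "same" else 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, p = self.kernel, self._pad()
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        patches = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,Ho,Wo,Cin,k,k
        z = np.tensordot(patches, self.W, axes=([3, 4, 5], [2, 0, 1])) + self.b
        z = np.ascontiguousarray(z, dtype=np.float32)
        if self.activation == "relu":
            y = relu(z)
            cache_act = z > 0
        elif self.activation == "gelu":
            y = gelu(z).astype(np.float32)
            cache_act = z
        elif self.activation == "sigmoid":
            y = sigmoid(z)
            cache_act = y
        elif self.activation is None:
            y, cache_act = z, None
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        if training:
            self._cache = (xp, cache_act)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, cache_act = self._cache
        if self.fused_head or self.activation is None:
            da = dy
        elif self.activation == "relu":
            da = dy * cache_act
        elif self.activation == "gelu":
            da = dy * _gelu_grad(cache_act)
        else:  # sigmoid, not fused
            da = dy * cache_act * (1.0 - cache_act)
        da = np.ascontiguousarray(da, dtype=np.float32)
        k = self.kernel
        patches = sliding_window_view(xp, (k, k), axis=(1, 2))
        dW = np.tensordot(patches, da, axes=([0, 1, 2], [0, 1, 2]))  # Cin,k,k,Cout
        self.dW = dW.transpose(1, 2, 0, 3).astype(np.float32)
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db = da.sum(axis=(0, 1, 2)).astype(np.float32)
        # input gradient = transposed convolution (full correlation with
        # spatially flipped kernels, in/out channels swapped)
        q = k - 1 - self._pad()
        dap = np.pad(da, ((0, 0), (q, q), (q, q), (0, 0))) if q else da
        dpat = sliding_window_view(dap, (k, k), axis=(1, 2))  # N,H,W,Cout,k,k
        Wf = self.W[::-1, ::-1]  # k,k,Cin,Cout
        dxp = np.tensordot(dpat, Wf, axes=([4, 5, 3], [0, 1, 3]))
        p = self._pad()
        if self.padding == "same" and p:
            dxp = dxp  # output already has the unpadded spatial size
        self._cache = None
        return np.ascontiguousarray(dxp, dtype=np.float32)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2.  Requires even spatial dims or crops the
    trailing row/column (Table-style shape ladders, e.g. 31 -> 15, do crop)."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2]
        r = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, idx)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, h, w, c), idx = self._cache
        h2, w2 = h // 2, w // 2
        out = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
        np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dy.dtype)
        dx[:, : h2 * 2, : w2 * 2] = (
            out.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h2 * 2, w2 * 2, c)
        )
        self._cache = None
        return dx


class UpSample2D(Layer):
    """2x nearest-neighbour upsampling (parameter-free)."""

    def __init__(self, name: str = "up"):
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer.  See Conv2D for the ``fused_head`` contract."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str | None = "relu",
        l2: float = 0.0,
        name: str = "dense",
        rng: np.random.Generator | None = None,
        fused_head: bool = False,
    ):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.activation = activation
        self.l2 = float(l2)
        self.name = name
        self.fused_head = fused_head
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    @property
    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            y, cache_act = relu(z), z > 0
        elif self.activation == "gelu":
            y, cache_act = gelu(z).astype(np.float32), z
        elif self.activation == "softmax":
            y, cache_act = softmax(z), None  # derivative fused into the loss
        elif self.activation == "sigmoid":
            y = sigmoid(z)
            cache_act = y
        elif self.activation is None:
            y, cache_act = z, None
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        if training:
            self._cache = (x, cache_act)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, cache_act = self._cache
        if self.fused_head or self.activation is None:
            da = dy
        elif self.activation == "relu":
            da = dy * cache_act
        elif self.activation == "gelu":
            da = dy * _gelu_grad(cache_act)
        elif self.activation == "sigmoid":
            da = dy * cache_act * (1.0 - cache_act)
        else:  # softmax without a fused loss is unsupported
            da = dy
        self.dW = (x.T @ da).astype(np.float32)
        if self.l2:
            self.dW += 2.0 * self.l2 * self.W
        self.db = da.sum(axis=0).astype(np.float32)
        self._cache = None
        return (da @ self.W.T).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, name: str = "dropout", rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.name = name
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask
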