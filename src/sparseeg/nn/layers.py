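"""Minimal seeded layer framework with explicit reverse-mode gradients.

Layers hold their parameters and gradients in plain dicts of ndarrays;
``forward`` caches whatever ``backward`` needs.  Convolutions are lowered to
im2col + matmul so the heavy lifting stays inside BLAS.  All initialization
draws from a caller-supplied ``numpy.random.Generator`` so a model is a pure
function of its seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: dtype of parameters and activations.  float32 keeps the memory-bound
#: elementwise stages fast; gradient-check tests switch to float64.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Layer:
    """Base class: parameters, gradients, and non-trainable buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self) -> list["Layer"]:
        return []


def iter_layers(root: Layer):
    yield root
    for child in root.children():
        yield from iter_layers(child)


def named_layers(root: Layer, prefix: str = "root"):
    yield prefix, root
    for i, child in enumerate(root.children()):
        yield from named_layers(child, f"{prefix}.{i}")


def state_dict(root: Layer, prefix: str = "root") -> dict[str, np.ndarray]:
    """Flat copy of every parameter and buffer, keyed by layer path."""
    out: dict[str, np.ndarray] = {}
    for name, layer in named_layers(root, prefix):
        for k, v in layer.params.items():
            out[f"{name}:{k}"] = v.copy()
        for k, v in layer.buffers.items():
            out[f"{name}:buf:{k}"] = v.copy()
    return out


def load_state_dict(root: Layer, state: dict[str, np.ndarray], prefix: str = "root") -> None:
    for name, layer in named_layers(root, prefix):
        for k in layer.params:
            src = state[f"{name}:{k}"]
            if src.shape != layer.params[k].shape:
                raise ValueError(f"shape mismatch for {name}:{k}")
            layer.params[k] = src.copy()
        for k in layer.buffers:
            layer.buffers[k] = state[f"{name}:buf:{k}"].copy()


def param_refs(root: Layer) -> list[tuple[Layer, str]]:
    """Stable (layer, key) references for the optimizer."""
    return [(layer, k) for layer in iter_layers(root) for k in sorted(layer.params)]


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Layer):
    """Valid (no-padding) 2-D convolution, fan-in-scaled uniform init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kh * kw
        self.params["w"] = _fan_in_uniform(rng, (out_ch, in_ch, kh, kw), fan_in)
        self.params["b"] = _fan_in_uniform(rng, (out_ch,), fan_in)

    def forward(self, x, training=False):
        kh, kw = self.kernel
        b, ci, h, w = x.shape
        if h < kh or w < kw:
            raise ValueError(f"input {x.shape} smaller than kernel {self.kernel}")
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,Ci,Ho,Wo,kh,kw
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, ci * kh * kw
        )
        wm = self.params["w"].reshape(self.out_ch, -1)
        out = cols @ wm.T + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        return out.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, xshape, ho, wo = self._cache
        b, ci, h, w = xshape
        kh, kw = self.kernel
        gm = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.grads["w"] = (gm.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] = gm.sum(axis=0)
        dcols = gm @ self.params["w"].reshape(self.out_ch, -1)
        dwin = dcols.reshape(b, ho, wo, ci, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(xshape, dtype=grad.dtype)
        for p in range(kh):
            for q in range(kw):
                dx[:, :, p : p + ho, q : q + wo] += dwin[:, :, :, :, p, q]
        return dx


class DepthwiseConv2d(Layer):
    """Valid depthwise convolution: one kernel per input channel."""

    def __init__(self, channels: int, kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.channels = channels
        fan_in = kh * kw
        self.params["w"] = _fan_in_uniform(rng, (channels, kh, kw), fan_in)
        self.params["b"] = _fan_in_uniform(rng, (channels,), fan_in)

    def forward(self, x, training=False):
        kh, kw = self.kernel
        if x.shape[2] < kh or x.shape[3] < kw:
            raise ValueError(f"input {x.shape} smaller than kernel {self.kernel}")
        win = sliding_window_view(x, (kh, kw), axis=(2, 3))
        out = np.einsum("bcijpq,cpq->bcij", win, self.params["w"], optimize=True)
        out += self.params["b"][None, :, None, None]
        self._cache = (win, x.shape)
        return out

    def backward(self, grad):
        win, xshape = self._cache
        kh, kw = self.kernel
        ho, wo = grad.shape[2], grad.shape[3]
        self.grads["w"] = np.einsum("bcij,bcijpq->cpq", grad, win, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        dx = np.zeros(xshape, dtype=grad.dtype)
        w = self.params["w"]
        for p in range(kh):
            for q in range(kw):
                dx[:, :, p : p + ho, q : q + wo] += grad * w[None, :, p, q, None, None]
        return dx


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x, training=False):
        self._factor = np.where(x > 0, x.dtype.type(1), x.dtype.type(self.negative_slope))
        return x * self._factor

    def backward(self, grad):
        return grad * self._factor


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(0.0)


class AvgPoolTime(Layer):
    """Average pooling over the trailing (time) axis, width == stride,
    floor division (a trailing remainder is dropped)."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x, training=False):
        w = x.shape[-1]
        wo = w // self.width
        if wo < 1:
            raise ValueError(f"time length {w} shorter than pool width {self.width}")
        self._in_len = w
        xt = x[..., : wo * self.width].reshape(*x.shape[:-1], wo, self.width)
        return xt.mean(axis=-1)

    def backward(self, grad):
        dx = np.zeros(grad.shape[:-1] + (self._in_len,), dtype=grad.dtype)
        wo = grad.shape[-1]
        expanded = np.repeat(grad[..., None] / grad.dtype.type(self.width), self.width, axis=-1)
        dx[..., : wo * self.width] = expanded.reshape(*grad.shape[:-1], wo * self.width)
        return dx


class MaxPoolTime(Layer):
    """Max pooling over the trailing axis, width == stride, floor division."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x, training=False):
        w = x.shape[-1]
        wo = w // self.width
        if wo < 1:
            raise ValueError(f"time length {w} shorter than pool width {self.width}")
        xt = x[..., : wo * self.width].reshape(*x.shape[:-1], wo, self.width)
        self._argmax = xt.argmax(axis=-1)
        self._in_len = w
        return xt.max(axis=-1)

    def backward(self, grad):
        wo = grad.shape[-1]
        dxt = np.zeros(grad.shape + (self.width,), dtype=grad.dtype)
        np.put_along_axis(dxt, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros(grad.shape[:-1] + (self._in_len,), dtype=grad.dtype)
        dx[..., : wo * self.width] = dxt.reshape(*grad.shape[:-1], wo * self.width)
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (axis 1 for
    >=3-D inputs, axis -1 for 2-D dense inputs)."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.n = n_features
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(n_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_features, dtype=DTYPE)
        self.buffers["running_mean"] = np.zeros(n_features, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(n_features, dtype=DTYPE)

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        shape = [1] * ndim
        shape[1 if ndim > 2 else -1] = self.n
        return tuple(shape)

    def forward(self, x, training=False):
        bshape = self._bshape(x.ndim)
        axes = tuple(i for i in range(x.ndim) if bshape[i] == 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = (1 - m) * self.buffers["running_mean"] + m * mean
            self.buffers["running_var"] = (1 - m) * self.buffers["running_var"] + m * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * ivar.reshape(bshape)
        self._cache = (xhat, ivar, axes, bshape, training)
        return self.params["gamma"].reshape(bshape) * xhat + self.params["beta"].reshape(bshape)

    def backward(self, grad):
        xhat, ivar, axes, bshape, training = self._cache
        gamma = self.params["gamma"].reshape(bshape)
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        dxhat = grad * gamma
        if not training:
            return dxhat * ivar.reshape(bshape)
        n = xhat.size // self.n
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (ivar.reshape(bshape) / n) * (n * dxhat - s1 - xhat * s2)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode.  Draws masks from its own
    generator so training runs are reproducible from the model seed."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep.astype(x.dtype) / x.dtype.type(1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _fan_in_uniform(rng, (out_features, in_features), in_features)
        self.params["b"] = _fan_in_uniform(rng, (out_features,), in_features)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, grad):
        self.grads["w"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"]


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class FlattenToSequence(Layer):
    """(B, C, H, W) → (B, 1, 1, C·H·W): collapse a 2-D feature map into a
    single-channel 1-D sequence (channel, then space, then time order)."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], 1, 1, -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ConcatBranches(Layer):
    """Run branches on the same input and concatenate outputs along ``axis``."""

    def __init__(self, branches: list[Layer], axis: int):
        super().__init__()
        self.branches = list(branches)
        self.axis = axis

    def children(self):
        return self.branches

    def forward(self, x, training=False):
        outs = [b.forward(x, training=training) for b in self.branches]
        self._sizes = [o.shape[self.axis] for o in outs]
        return np.concatenate(outs, axis=self.axis)

    def backward(self, grad):
        splits = np.cumsum(self._sizes)[:-1]
        parts = np.split(grad, splits, axis=self.axis)
        dx = None
        for branch, g in zip(self.branches, parts):
            d = branch.backward(np.ascontiguousarray(g))
            dx = d if dx is None else dx + d
        return dx
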