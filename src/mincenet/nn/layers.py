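"""Minimal NumPy layer stack with explicit forward/backward passes.

Every layer caches what its backward pass needs only when ``training=True``,
so inference on large models stays memory-light.  Convolutions follow the
Keras accounting convention used throughout the package: pointwise and full
convolutions carry biases, depthwise convolutions default to bias-free, and
batch normalisation holds two trainable parameters plus two moving statistics
per channel.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "Dense",
    "ReLU",
    "ReLU6",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool",
]


class Parameter:
    """A named weight array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    """Base class: a node in the layer tree."""

    #: set True to freeze: parameters stop training and batch-norm layers
    #: switch to their moving statistics even during training.
    frozen: bool = False

    def sublayers(self):
        """Ordered ``(name, layer)`` children."""
        return []

    def own_parameters(self):
        return []

    def own_buffers(self):
        """Non-trainable state (name, array), e.g. batch-norm statistics."""
        return []

    def parameters(self):
        params = list(self.own_parameters())
        for _, sub in self.sublayers():
            params.extend(sub.parameters())
        return params

    def walk(self, prefix: str = ""):
        """Depth-first ``(qualified_name, layer)`` traversal."""
        name = prefix or type(self).__name__.lower()
        yield name, self
        for child_name, sub in self.sublayers():
            yield from sub.walk(f"{name}/{child_name}")

    def set_frozen(self, flag: bool = True):
        self.frozen = flag
        for p in self.own_parameters():
            p.trainable = not flag
        for _, sub in self.sublayers():
            sub.set_frozen(flag)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def sublayers(self):
        return [(f"{i}_{type(l).__name__.lower()}", l) for i, l in enumerate(self.layers)]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def _extract_patches(xp: np.ndarray, k: int, stride: int, h_out: int, w_out: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,k,k,Ho,Wo) by slice gathering (no Python per-pixel loops)."""
    n, c = xp.shape[:2]
    out = np.empty((n, c, k, k, h_out, w_out), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i, j] = xp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride]
    return out


def _scatter_patches(dpatch: np.ndarray, xp_shape, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_extract_patches` (overlap-add)."""
    dxp = np.zeros(xp_shape, dtype=dpatch.dtype)
    h_out, w_out = dpatch.shape[-2:]
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += dpatch[:, :, i, j]
    return dxp


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution; kernel 1 uses a fast channel-matmul path."""

    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, bias=True,
                 rng: np.random.Generator | None = None, name="conv"):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = int(c_in), int(c_out)
        self.kernel, self.stride, self.padding = int(kernel), int(stride), int(padding)
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(f"{name}.weight", he_normal(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(f"{name}.bias", np.zeros(c_out, dtype=np.float32)) if bias else None
        self._cache = None

    def own_parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_hw(self, h, w):
        k, s, p = self.kernel, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = self._out_hw(h, w)
        w2 = self.weight.value.reshape(self.c_out, -1)
        if k == 1:
            xs = x[:, :, ::s, ::s][:, :, :ho, :wo]
            cols = xs.reshape(n, c, ho * wo)
            self._cache = (cols, (n, c, h, w)) if training else None
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
            patches = _extract_patches(xp, k, s, ho, wo)
            cols = patches.reshape(n, c * k * k, ho * wo)
            self._cache = (cols, (n, c, h, w)) if training else None
        y = np.matmul(w2, cols).reshape(n, self.c_out, ho, wo)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        if self._cache is None:
            raise RuntimeError("backward called without a training forward pass")
        cols, (n, c, h, w) = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = dy.shape[-2:]
        dyf = dy.reshape(n, self.c_out, ho * wo)
        self.weight.grad += np.einsum("nol,nkl->ok", dyf, cols, optimize=True).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        w2 = self.weight.value.reshape(self.c_out, -1)
        dcols = np.matmul(w2.T, dyf)
        if k == 1:
            dx = np.zeros((n, c, h, w), dtype=dy.dtype)
            dx[:, :, : s * ho : s, : s * wo : s] = dcols.reshape(n, c, ho, wo)
            return dx
        dpatch = dcols.reshape(n, c, k, k, ho, wo)
        dxp = _scatter_patches(dpatch, (n, c, h + 2 * p, w + 2 * p), k, s)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class DepthwiseConv2d(Layer):
    def __init__(self, channels, kernel=3, stride=1, padding=1, bias=False,
                 rng: np.random.Generator | None = None, name="dwconv"):
        rng = rng or np.random.default_rng(0)
        self.channels, self.kernel = int(channels), int(kernel)
        self.stride, self.padding = int(stride), int(padding)
        self.weight = Parameter(f"{name}.weight", he_normal(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(f"{name}.bias", np.zeros(channels, dtype=np.float32)) if bias else None
        self._cache = None

    def own_parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # k*k fused multiply-adds over shifted views; no patch tensor is built
        wv = self.weight.value
        y = np.zeros((n, c, ho, wo), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y += xp[:, :, i : i + s * ho : s, j : j + s * wo : s] * wv[None, :, i, j, None, None]
        self._cache = (xp, (n, c, h, w), (ho, wo)) if training else None
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        return y

    def backward(self, dy):
        xp, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        wv = self.weight.value
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, :, i : i + s * ho : s, j : j + s * wo : s]
                self.weight.grad[:, i, j] += (dy * xp[sl]).sum(axis=(0, 2, 3))
                dxp[sl] += dy * wv[None, :, i, j, None, None]
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    """Channel-wise batch normalisation (2c trainable + 2c moving statistics)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5, name="bn"):
        self.channels = int(channels)
        self.momentum, self.eps = float(momentum), float(eps)
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=np.float32))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def own_parameters(self):
        return [self.gamma, self.beta]

    def own_buffers(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x, training=False):
        use_batch_stats = training and not self.frozen
        if use_batch_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean *= m
            self.running_mean += (1 - m) * mean
            self.running_var *= m
            self.running_var += (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if training:
            self._cache = (xhat, invstd, use_batch_stats)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, invstd, used_batch = self._cache
        n, _, h, w = dy.shape
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = (self.gamma.value * invstd)[None, :, None, None]
        if not used_batch:
            return dy * g
        m = n * h * w
        dyxhat_sum = (dy * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        dy_sum = dy.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return g * (dy - dy_sum / m - xhat * dyxhat_sum / m)


class Dense(Layer):
    def __init__(self, f_in, f_out, bias=True, rng: np.random.Generator | None = None, name="dense"):
        rng = rng or np.random.default_rng(0)
        self.f_in, self.f_out = int(f_in), int(f_out)
        self.weight = Parameter(f"{name}.weight", he_normal(rng, (f_out, f_in), f_in))
        self.bias = Parameter(f"{name}.bias", np.zeros(f_out, dtype=np.float32)) if bias else None
        self._cache = None

    def own_parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        self._cache = x if training else None
        y = x @ self.weight.value.T
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, dy):
        x = self._cache
        self.weight.grad += dy.T @ x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


class ReLU(Layer):
    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, dy):
        return dy * self._mask


class ReLU6(Layer):
    """Bounded rectifier used inside inverted residual blocks."""

    def forward(self, x, training=False):
        y = np.clip(x, 0, 6)
        self._mask = (x > 0) & (x < 6) if training else None
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y if training else None
        return y

    def backward(self, dy):
        return dy * self._y * (1 - self._y)


class MaxPool2d(Layer):
    def __init__(self, kernel=3, stride=2, padding=1):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        patches = _extract_patches(xp, k, s, ho, wo).reshape(n, c, k * k, ho, wo)
        arg = patches.argmax(axis=2)
        y = np.take_along_axis(patches, arg[:, :, None], axis=2)[:, :, 0]
        if training:
            self._cache = (arg, (n, c, h, w))
        return y

    def backward(self, dy):
        arg, (n, c, h, w) = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        ho, wo = dy.shape[-2:]
        dpatch = np.zeros((n, c, k * k, ho, wo), dtype=dy.dtype)
        np.put_along_axis(dpatch, arg[:, :, None], dy[:, :, None], axis=2)
        dxp = _scatter_patches(dpatch.reshape(n, c, k, k, ho, wo), (n, c, h + 2 * p, w + 2 * p), k, s)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, training=False):
        self._hw = x.shape[-2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)).copy() / (h * w)
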