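"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Internally tensors are NCHW ``(batch, maps, height, width)``; the public
feature-tensor convention at the package boundary is ``[row, column, map]``
(see :mod:`fpnets.fp_block`).  Every layer caches what its backward pass
needs during ``forward`` and releases it on the next call.  Gradients are
accumulated into ``Param.grad``; call :meth:`Layer.zero_grad` between steps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "InstanceNorm2d",
    "ReLU",
    "ReLU6",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool",
    "Sequential",
    "SoftmaxCrossEntropy",
    "SGD",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: ``forward(x, train)`` -> y, ``backward(dy)`` -> dx."""

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> view (N, C, Ho, Wo, k, k) of k x k patches."""
    v = sliding_window_view(x, (k, k), axis=(2, 3))
    if stride > 1:
        v = v[:, :, ::stride, ::stride]
    return v


def _dilate_and_pad(dy: np.ndarray, stride: int, k: int, p: int, h_in: int, w_in: int) -> np.ndarray:
    """Prepare an output gradient for the transposed-convolution input pass.

    Inserts ``stride - 1`` zeros between gradient pixels and pads so that a
    valid correlation with the spatially flipped kernel yields exactly the
    (padded-input-cropped) input gradient.
    """
    n, c, ho, wo = dy.shape
    hd, wd = (ho - 1) * stride + 1, (wo - 1) * stride + 1
    # leftover rows/cols of the padded input never hit by a kernel placement
    ah = h_in + 2 * p - k - (ho - 1) * stride
    aw = w_in + 2 * p - k - (wo - 1) * stride
    up = np.zeros((n, c, hd, wd), dtype=dy.dtype)
    up[:, :, ::stride, ::stride] = dy
    e = k - 1 - p
    return np.pad(up, ((0, 0), (0, 0), (e, e + ah), (e, e + aw)))


class Conv2d(Layer):
    """2-D cross-correlation, same-family padding, optional bias.

    Weight shape ``(c_out, c_in, k, k)``; He-normal initialisation.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param((rng.standard_normal((c_out, c_in, k, k)) * std).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x, train=False):
        xp = _pad_hw(x, self.pad)
        cols = _windows(xp, self.k, self.stride)
        y = np.tensordot(cols, self.W.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        self._cache = (cols, x.shape)
        return y

    def backward(self, dy):
        cols, x_shape = self._cache
        self._cache = None
        self.W.grad += np.tensordot(dy, cols, axes=([0, 2, 3], [0, 2, 3]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        h, w = x_shape[2], x_shape[3]
        up = _dilate_and_pad(dy, self.stride, self.k, self.pad, h, w)
        wf = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        cols_b = _windows(up, self.k, 1)
        dx = np.tensordot(cols_b, wf, axes=([1, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)  # (N, c_in, h, w) by construction of the padding


class DepthwiseConv2d(Layer):
    """Per-map (depthwise-separable) k x k correlation; weights ``(c, k, k)``."""

    def __init__(self, c: int, k: int = 3, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.c, self.k, self.stride = c, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (k * k))
        self.W = Param((rng.standard_normal((c, k, k)) * std).astype(dtype))
        self._cache = None

    def forward(self, x, train=False):
        xp = _pad_hw(x, self.pad)
        cols = _windows(xp, self.k, self.stride)  # (N, C, Ho, Wo, k, k)
        y = np.einsum("ncijuv,cuv->ncij", cols, self.W.value, optimize=True)
        self._cache = (cols, x.shape)
        return y

    def backward(self, dy):
        cols, x_shape = self._cache
        self._cache = None
        self.W.grad += np.einsum("ncij,ncijuv->cuv", dy, cols, optimize=True)
        h, w = x_shape[2], x_shape[3]
        up = _dilate_and_pad(dy, self.stride, self.k, self.pad, h, w)
        wf = self.W.value[:, ::-1, ::-1]
        cols_b = _windows(up, self.k, 1)
        dx = np.einsum("ncijuv,cuv->ncij", cols_b, wf, optimize=True)
        return np.ascontiguousarray(dx)


class BatchNorm2d(Layer):
    """Batch normalisation with affine parameters and running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return y

    def backward(self, dy):
        xhat, inv, train, x_shape = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        n = x_shape[0] * x_shape[2] * x_shape[3]
        dxhat = dy * g
        mean_d = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (dxhat - mean_d - xhat * mean_dx)


class InstanceNorm2d(Layer):
    """Per-sample, per-map standardisation without affine parameters.

    Divides by ``sigma + eps`` (the standard deviation itself, not
    ``sqrt(var + eps)``), so constant maps are mapped to exactly zero.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=(2, 3), keepdims=True)
        sigma = x.std(axis=(2, 3), keepdims=True)
        s = sigma + self.eps
        xc = x - mu
        y = xc / s
        self._cache = (xc, sigma, s)
        return y

    def backward(self, dy):
        xc, sigma, s = self._cache
        self._cache = None
        n = xc.shape[2] * xc.shape[3]
        mean_dy = dy.mean(axis=(2, 3), keepdims=True)
        corr = (dy * xc).sum(axis=(2, 3), keepdims=True)
        sigma_safe = np.maximum(sigma, 1e-30)
        return (dy - mean_dy) / s - xc * corr / (n * s * s * sigma_safe)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        mask, self._mask = self._mask, None
        return np.where(mask, dy, 0.0)


class ReLU6(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dy):
        mask, self._mask = self._mask, None
        return np.where(mask, dy, 0.0)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_out, n_in)) * std).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype)) if bias else None
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.W.value.T
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dy):
        x, self._x = self._x, None
        self.W.grad += dy.T @ x
        if self.b is not None:
            self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        xp = _pad_hw(x, self.pad)
        if self.pad:
            xp[:, :, :self.pad, :] = -np.inf
            xp[:, :, -self.pad:, :] = -np.inf
            xp[:, :, :, :self.pad] = -np.inf
            xp[:, :, :, -self.pad:] = -np.inf
        cols = _windows(xp, self.k, self.stride)
        n, c, ho, wo = cols.shape[:4]
        flat = cols.reshape(n, c, ho, wo, -1)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape)
        return y

    def backward(self, dy):
        idx, x_shape, xp_shape = self._cache
        self._cache = None
        n, c, h, w = x_shape
        dxp = np.zeros((n, c) + xp_shape[2:], dtype=dy.dtype)
        ho, wo = dy.shape[2], dy.shape[3]
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        u, v = idx // self.k, idx % self.k
        rows = ii[None, None] * self.stride + u
        colz = jj[None, None] * self.stride + v
        nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dxp, (nn_[:, :, None, None], cc[:, :, None, None], rows, colz), dy)
        p = self.pad
        return dxp[:, :, p:p + h, p:p + w]


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SoftmaxCrossEntropy:
    """Mean cross-entropy over a batch of logits; backward returns dlogits."""

    def __init__(self):
        self._cache = None

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        n = logits.shape[0]
        loss = -logp[np.arange(n), labels].mean()
        self._cache = (np.exp(logp), labels)
        return float(loss)

    def backward(self) -> np.ndarray:
        probs, labels = self._cache
        self._cache = None
        n = probs.shape[0]
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        return d / n


class SGD:
    """Plain SGD with momentum and optional weight decay."""

    def __init__(self, params: list[Param], lr: float = 0.05, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= (self.lr * v).astype(p.value.dtype, copy=False)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
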