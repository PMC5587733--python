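"""Minimal convolutional network engine.

Implements the layers the dual-path architecture needs — 2-D convolution,
batch normalization, ReLU, average pooling, global average pooling and a
dense head — each with an explicit backward pass, plus softmax
cross-entropy and SGD with momentum.  Everything is plain numpy: forward
convolution is an im2col matrix product and the gradient w.r.t. the input
is accumulated with k*k strided slice additions, which keeps both
directions BLAS-bound.

All computation is deterministic: parameter initialisation draws from a
``numpy.random.Generator`` supplied by the caller and no other source of
randomness exists in the engine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Parallel",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # weight decay applies (False for biases / BN)


class Layer:
    """Base layer: forward caches what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> windows (N,Ho,Wo,C*k*k); returns (cols, Ho, Wo, Hp, Wp)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = h + 2 * pad, w + 2 * pad
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo, hp, wp


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col. dcols: (N,Ho,Wo,C,k,k)."""
    n, c, h, w = x_shape
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,k,k
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Layer):
    """2-D convolution with 'same' padding (pad = k // 2).

    With stride 2 and odd k the output side is ceil(S / 2).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype), decay=False) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        cols, ho, wo, _, _ = _im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.w.value.T
        if self.b is not None:
            out += self.b.value
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad):
        cols, x_shape = self._cache
        n, ho, wo, _ = cols.shape
        g = grad.transpose(0, 2, 3, 1)  # N,Ho,Wo,c_out
        gf = g.reshape(-1, self.c_out)
        self.w.grad += gf.T @ cols.reshape(-1, cols.shape[-1])
        if self.b is not None:
            self.b.grad += gf.sum(axis=0)
        dcols = (g @ self.w.value).reshape(n, ho, wo, self.c_in, self.k, self.k)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(c, dtype=dtype), decay=False)
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        ax = (0, 2, 3)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * mean
            self.run_var = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        ax = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=ax)
        self.beta.grad += grad.sum(axis=ax)
        g = grad * self.gamma.value[None, :, None, None]
        gs = g.sum(axis=ax)
        gxs = (g * xhat).sum(axis=ax)
        dx = (
            g
            - gs[None, :, None, None] / n_eff
            - xhat * gxs[None, :, None, None] / n_eff
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool2d(Layer):
    """k x k average pooling, 'same' padding; pad pixels count in the mean."""

    def __init__(self, k: int = 3, stride: int = 1):
        self.k, self.stride, self.pad = k, stride, k // 2
        self._cache = None

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        win = sliding_window_view(
            np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad))),
            (self.k, self.k),
            axis=(2, 3),
        )[:, :, :: self.stride, :: self.stride]
        out = win.mean(axis=(4, 5))
        self._cache = (x.shape, out.shape)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        x_shape, out_shape = self._cache
        n, c, ho, wo = out_shape
        scale = 1.0 / (self.k * self.k)
        dcols = np.broadcast_to(
            (grad * scale).transpose(0, 2, 3, 1)[:, :, :, :, None, None],
            (n, ho, wo, c, self.k, self.k),
        )
        return _col2im(np.ascontiguousarray(dcols), x_shape, self.k, self.stride, self.pad)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).copy()


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype), decay=False)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Parallel(Layer):
    """Run branches on the same input and concatenate along channels."""

    def __init__(self, branches: list[Layer]):
        self.branches = list(branches)
        self._splits = None

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def forward(self, x, train=True):
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        parts = np.split(grad, self._splits, axis=1)
        total = None
        for b, g in zip(self.branches, parts):
            d = b.backward(np.ascontiguousarray(g))
            total = d if total is None else total + d
        return total


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
):
    """Mean weighted cross-entropy; returns (loss, dlogits, probs)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    w = np.ones(n) if class_weights is None else class_weights[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = -(w * logp).sum() / w.sum()
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    d *= (w / w.sum())[:, None]
    return loss, d.astype(logits.dtype), p


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v
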