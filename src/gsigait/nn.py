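"""Minimal NumPy neural-network core for the recognition harness.

Implements exactly the pieces the two-block gait CNN needs — 2D valid
convolution (im2col + BLAS matmul), batch normalization, ReLU, 2x2 max
pooling, fully connected layers, inverted dropout, softmax cross-entropy —
plus AdamW with a warm-up/cosine learning-rate schedule.  Forward and
backward passes are hand-derived; everything is deterministic given the
generator passed in at construction.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "softmax_cross_entropy",
    "AdamW",
    "warmup_cosine_lr",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Valid (no padding, stride 1) 2D convolution."""

    def __init__(self, in_c: int, out_c: int, k: int, rng: np.random.Generator):
        fan_in = in_c * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_c, in_c, k, k)).astype(np.float32))
        self.b = Param(np.zeros(out_c, dtype=np.float32))
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, c, h, w = x.shape
        k = self.k
        cols = sliding_window_view(x, (k, k), axis=(2, 3))  # (n, c, ho, wo, k, k)
        ho, wo = cols.shape[2], cols.shape[3]
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        self._cols, self._shape = cols, (n, c, h, w, ho, wo)
        out = cols @ self.W.value.reshape(self.W.value.shape[0], -1).T + self.b.value
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w, ho, wo = self._shape
        k = self.k
        oc = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, oc)
        self.W.grad += (dflat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.reshape(oc, -1)).reshape(n, ho, wo, c, k, k)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        if not self._train:
            return dout * (self.gamma.value * inv)[None, :, None, None]
        dxhat = dout * self.gamma.value[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are cropped."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        self._mask = xc == out[:, :, :, None, :, None]
        self._shape = (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        spread = self._mask * dout[:, :, :, None, :, None]
        dx[:, :, : 2 * h2, : 2 * w2] = spread.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at eval."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_until(self, x, stop_index: int, train=False):
        """Forward through layers [0, stop_index) — used for embeddings."""
        for layer in self.layers[:stop_index]:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: List[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.value)


def warmup_cosine_lr(epoch: int, max_epochs: int, base_lr: float, warmup: int = 5) -> float:
    """Linear warm-up over the first `warmup` epochs, cosine decay after."""
    if epoch < warmup:
        return base_lr * (epoch + 1) / warmup
    span = max(1, max_epochs - warmup)
    return base_lr * 0.5 * (1 + np.cos(np.pi * (epoch - warmup) / span))
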