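"""Minimal feed-forward neural-network primitives on numpy.

Implements exactly the pieces the activity-prediction networks need —
1-D convolution with length-preserving zero padding, average pooling,
dense layers, ReLU, dropout, a two-row embedding, the Adam optimizer
and a mean-absolute-error loss — with explicit forward/backward passes.
Shapes are channels-first: sequence inputs are (batch, channels,
length).

All randomness (initialization, dropout masks, batch shuffling) flows
through a single ``numpy.random.Generator`` so training runs are
reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "AvgPool1D",
    "ReLU",
    "Dropout",
    "Embedding",
    "Adam",
    "mae_loss",
]


class Layer:
    """Base class: layers expose params/grads lists for the optimizer."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Conv1D(Layer):
    """Cross-correlation over (batch, channels, length) with zero
    padding chosen to preserve length (odd kernel widths)."""

    def __init__(self, c_in: int, filters: int, width: int, rng: np.random.Generator):
        if width % 2 != 1:
            raise ValueError("kernel width must be odd for length-preserving padding")
        scale = np.sqrt(2.0 / (c_in * width))
        self.w = rng.normal(0.0, scale, size=(c_in * width, filters)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.c_in = c_in
        self.width = width
        self.filters = filters

    def _patch_index(self, length: int) -> np.ndarray:
        half = self.width // 2
        # indices into the padded axis, one row per output position
        return np.arange(length)[:, None] + np.arange(self.width)[None, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, length = x.shape
        half = self.width // 2
        xp = np.pad(x, ((0, 0), (0, 0), (half, half)))
        idx = self._patch_index(length)
        # (B, C, L, K) -> (B, L, C*K)
        patches = xp[:, :, idx].transpose(0, 2, 1, 3).reshape(b, length, -1)
        self._patches = patches
        self._in_shape = x.shape
        y = patches @ self.w + self.b  # (B, L, F)
        return y.transpose(0, 2, 1)  # (B, F, L)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, length = self._in_shape
        gl = g.transpose(0, 2, 1)  # (B, L, F)
        flat_p = self._patches.reshape(-1, self.c_in * self.width)
        flat_g = gl.reshape(-1, self.filters)
        self.dw[...] = flat_p.T @ flat_g
        self.db[...] = flat_g.sum(axis=0)
        gpatch = (flat_g @ self.w.T).reshape(b, length, self.c_in, self.width)
        half = self.width // 2
        gx = np.zeros((b, c, length + 2 * half), dtype=g.dtype)
        idx = self._patch_index(length)
        np.add.at(gx, (slice(None), slice(None), idx), gpatch.transpose(0, 2, 1, 3))
        return gx[:, :, half : half + length]

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class AvgPool1D(Layer):
    def __init__(self, width: int = 2, stride: int | None = None):
        self.width = width
        self.stride = stride if stride is not None else width
        if self.stride != self.width:
            raise ValueError("only non-overlapping pooling is supported")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, length = x.shape
        n = length // self.width
        self._in_shape = x.shape
        self._n = n
        return x[:, :, : n * self.width].reshape(b, c, n, self.width).mean(axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, length = self._in_shape
        gx = np.zeros(self._in_shape, dtype=g.dtype)
        expanded = np.repeat(g / np.asarray(self.width, dtype=g.dtype), self.width, axis=2)
        gx[:, :, : self._n * self.width] = expanded
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = self.rng.random(x.shape) >= self.rate
        self._mask = keep.astype(x.dtype) / np.asarray(1.0 - self.rate, dtype=x.dtype)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


class Embedding(Layer):
    """Integer-indexed lookup table of learned vectors."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, 1.0, size=(n_rows, dim)).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def forward(self, idx: np.ndarray, train: bool = False) -> np.ndarray:
        self._idx = np.asarray(idx, dtype=int)
        return self.w[self._idx]

    def backward(self, g: np.ndarray) -> None:
        self.dw[...] = 0.0
        np.add.at(self.dw, self._idx, g)

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]


class Adam:
    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad
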