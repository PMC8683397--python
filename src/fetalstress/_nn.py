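"""Minimal deterministic numpy neural-network core.

Implements exactly the pieces the two-stage pipeline needs: 1-D 'same'
convolutions (im2col + BLAS), leaky-ReLU, max / global-max pooling, dense
layers, inverted dropout, the Adam optimizer and the binary-cross-entropy /
mean-absolute-error losses.  Everything is float32 and seeded through
explicitly passed generators, so training trajectories are bit-reproducible
on one machine.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """'Same'-padded cross-correlation, x: (N, C, L) -> (N, O, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = (scale * rng.standard_normal((c_out, c_in, kernel))).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k = kernel
        self.pl = (kernel - 1) // 2

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        k, pl = self.k, self.pl
        xp = np.pad(x, ((0, 0), (0, 0), (pl, k - 1 - pl)))
        self._win = sliding_window_view(xp, k, axis=2)  # (N, C, L, k)
        y = np.tensordot(self._win, self.W, axes=([1, 3], [1, 2]))  # (N, L, O)
        return (y + self.b).transpose(0, 2, 1).astype(DTYPE, copy=False)

    def backward(self, g):
        # g: (N, O, L)
        k, pl = self.k, self.pl
        self.gW[...] = np.tensordot(g, self._win, axes=([0, 2], [0, 2]))
        self.gb[...] = g.sum(axis=(0, 2))
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = sliding_window_view(gp, k, axis=2)  # (N, O, L+k-1, k)
        wflip = self.W[:, :, ::-1]
        gxp = np.tensordot(gwin, wflip, axes=([1, 3], [0, 2]))  # (N, L+k-1, C)
        gxp = gxp.transpose(0, 2, 1)
        L = g.shape[2]
        return gxp[:, :, pl : pl + L].astype(DTYPE, copy=False)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class MaxPool1d(Layer):
    """Non-overlapping pooling along time; truncates a ragged tail."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        n, c, L = x.shape
        m = L // self.size
        self._in_shape = x.shape
        xr = x[:, :, : m * self.size].reshape(n, c, m, self.size)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        n, c, L = self._in_shape
        m = g.shape[2]
        gx = np.zeros((n, c, m, self.size), dtype=DTYPE)
        np.put_along_axis(gx, self._arg[..., None], g[..., None], axis=3)
        out = np.zeros(self._in_shape, dtype=DTYPE)
        out[:, :, : m * self.size] = gx.reshape(n, c, m * self.size)
        return out


class GlobalMaxPool(Layer):
    """(N, C, L) -> (N, C) over time."""

    def forward(self, x, train):
        self._in_shape = x.shape
        self._arg = x.argmax(axis=2)
        return x.max(axis=2)

    def backward(self, g):
        gx = np.zeros(self._in_shape, dtype=DTYPE)
        n, c, _ = self._in_shape
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gx[ii, jj, self._arg] = g
        return gx


class Scale(Layer):
    """Fixed (non-learned) gain; sets the feature magnitude the readout
    heads see, which controls how fast a fixed-lr optimizer can move
    logits."""

    def __init__(self, gain: float):
        self.gain = DTYPE(gain)

    def forward(self, x, train):
        return x * self.gain

    def backward(self, g):
        return g * self.gain


class Dense(Layer):
    """Fully connected layer.  ``init_scale=None`` gives He initialization;
    readout layers pass 0.0 so initial logits start at zero and the whole
    optimization budget goes into discrimination."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        scale = np.sqrt(2.0 / d_in) if init_scale is None else init_scale
        self.W = (scale * rng.standard_normal((d_in, d_out))).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return (g @ self.W.T).astype(DTYPE, copy=False)


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def grads(self):
        return [g for lay in self.layers for g in lay.grads()]

    def forward(self, x, train):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0:
            return
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(
    z: np.ndarray, y: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy; returns (loss, dloss/dz).

    ``pos_weight`` rescales the positive-class terms (the weights are
    normalized to sum to one), compensating structural class imbalance such
    as the one-positive-in-(k+1) layout of multi-head pretext labels.
    """
    z = z.astype(np.float64)
    w = np.where(y == 1, pos_weight, 1.0)
    w = w / w.sum()
    loss = np.sum(w * (np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = w * (sigmoid(z) - y)
    return float(loss), grad.astype(DTYPE)


def mae_loss(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    d = p.astype(np.float64) - y
    return float(np.mean(np.abs(d))), (np.sign(d) / d.size).astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weights_checksum(params: list[np.ndarray]) -> str:
    """SHA-256 over the concatenated parameter bytes (freeze contract)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()
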