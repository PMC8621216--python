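"""Minimal convolutional-network engine on numpy.

Implements exactly the layers the frame classifier needs — 3x3
single-stride convolution, ReLU, 2x2 max-pooling, global average
pooling, dropout, a dense head and a softmax/cross-entropy loss —
with explicit forward/backward passes and an Adam optimizer.
Convolutions are lowered to BLAS GEMMs via im2col, so a single CPU
core sustains training at 128x128 input. All arrays are float32,
layout (batch, channels, height, width).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Dropout",
    "Dense",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]

_F32 = np.float32


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (spatial-preserving).

    Evaluated as nine (filters x channels) GEMMs against shifted views
    of the padded input — equivalent to im2col + GEMM but without the
    9x column buffer, which keeps the layer BLAS-bound on one core.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # He initialization for ReLU networks
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((b, self.w.shape[0], h * w), dtype=_F32)
        for di in range(3):
            for dj in range(3):
                wk = np.ascontiguousarray(self.w[:, :, di, dj])  # (F, C)
                xs = np.ascontiguousarray(
                    xp[:, :, di : di + h, dj : dj + w]
                ).reshape(b, c, h * w)
                out += wk @ xs
        out += self.b[:, None]
        if train:
            self._cache = (xp, (b, c, h, w))
        return out.reshape(b, -1, h, w)

    def backward(self, dout: np.ndarray):
        xp, (b, c, h, w) = self._cache
        self._cache = None
        f = dout.shape[1]
        d2 = dout.reshape(b, f, h * w)
        dw = np.empty_like(self.w)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = np.ascontiguousarray(
                    xp[:, :, di : di + h, dj : dj + w]
                ).reshape(b, c, h * w)
                # sum over batch of dout_b @ xs_b^T
                dw[:, :, di, dj] = np.matmul(d2, xs.transpose(0, 2, 1)).sum(axis=0)
                wk = np.ascontiguousarray(self.w[:, :, di, dj])
                dxs = (wk.T @ d2).reshape(b, c, h, w)
                dxp[:, :, di : di + h, dj : dj + w] += dxs
        db = d2.sum(axis=(0, 2))
        return dxp[:, :, 1:-1, 1:-1], [dw, db]


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        m = self._mask
        self._mask = None
        return dout * m, []


class MaxPool2x2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        xr = (
            x.reshape(b, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h // 2, w // 2, 4)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, (b, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        return dx, []


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    params: list = []

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        b, c, h, w = self._shape
        dx = np.broadcast_to(dout[:, :, None, None] / (h * w), (b, c, h, w))
        return np.ascontiguousarray(dx), []


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    params: list = []

    def forward(self, x, train=False, rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / _F32(keep)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout, []
        m = self._mask
        self._mask = None
        return dout * m, []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        x = self._x
        self._x = None
        dw = dout.T @ x
        db = dout.sum(axis=0)
        dx = dout @ self.w
        return dx, [dw, db]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray, sample_weight=None):
    """Mean weighted cross-entropy and its gradient w.r.t. logits.

    y: integer class labels. Returns (loss, dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ll = -np.log(p[np.arange(n), y] + eps)
    if sample_weight is None:
        sample_weight = np.ones(n)
    wsum = sample_weight.sum()
    loss = float((ll * sample_weight).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (sample_weight / wsum)[:, None]
    return loss, dlogits.astype(_F32)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)
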