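"""Minimal seeded neural-network primitives on NumPy.

Float32 throughout; every layer implements ``forward`` and ``backward`` with
explicit caches, and exposes its parameters as :class:`Param` objects so a
single optimiser can update a whole model. Activations are kept channels-last
(batch, rows, cols, channels): with that layout the im2col windows of a
'same'-padded convolution are already in GEMM order, so each direction is one
matrix product plus a single packing copy.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Conv2d:
    """2-D convolution with 'same' zero padding (pad = kernel // 2).

    Both directions are evaluated as one im2col GEMM, which is where nearly
    all the arithmetic of the model lives.
    """

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int], rng):
        kh, kw = kernel
        fan_in = c_in * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kh, kw))
        self.w = Param(w, "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b")
        self.kernel = kernel
        self.pad = (kh // 2, kw // 2)
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _kmat(self) -> np.ndarray:
        # (C*kh*kw, F) layout matching the im2col column order
        f = self.w.value.shape[0]
        return self.w.value.reshape(f, -1).T

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x is channels-last: (B, H, W, C)."""
        kh, kw = self.kernel
        ph, pw = self.pad
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        # windows over the spatial axes land in (B, H, W, C, kh, kw) order,
        # which is exactly the im2col column layout
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = win.reshape(b * h * w, c * kh * kw)
        y = cols @ self._kmat() + self.b.value
        self._cache = (cols, (b, h, w, c))
        return y.reshape(b, h, w, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (b, h, w, c) = self._cache
        kh, kw = self.kernel
        ph, pw = self.pad
        f = dy.shape[-1]
        dyt = dy.reshape(b * h * w, f)
        dk = cols.T @ dyt  # (C*kh*kw, F)
        self.w.grad += dk.T.reshape(self.w.value.shape)
        self.b.grad += dyt.sum(axis=0)
        dcols = (dyt @ self._kmat().T).reshape(b, h, w, c, kh, kw)
        dxp = np.zeros((b, h + 2 * ph, w + 2 * pw, c), dtype=F32)
        for u in range(kh):
            for v in range(kw):
                dxp[:, u : u + h, v : v + w, :] += dcols[:, :, :, :, u, v]
        if ph or pw:
            return dxp[:, ph : ph + h, pw : pw + w, :]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy):
        return np.where(self._mask, dy, F32(0.0))


class MaxPool2d:
    """Non-overlapping max pooling; kernel is clamped to the input size and
    trailing remainder rows/columns are dropped."""

    def __init__(self, kernel: tuple[int, int] = (2, 2)):
        self.kernel = kernel
        self._cache = None

    def forward(self, x):
        b, h, w, c = x.shape
        kh = min(self.kernel[0], h)
        kw = min(self.kernel[1], w)
        ho, wo = h // kh, w // kw
        xr = (
            x[:, : ho * kh, : wo * kw, :]
            .reshape(b, ho, kh, wo, kw, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, ho, wo, c, kh * kw)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, (kh, kw), idx)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        (b, h, w, c), (kh, kw), idx = self._cache
        ho, wo = dy.shape[1], dy.shape[2]
        dxr = np.zeros((b, ho, wo, c, kh * kw), dtype=F32)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((b, h, w, c), dtype=F32)
        dx[:, : ho * kh, : wo * kw, :] = (
            dxr.reshape(b, ho, wo, c, kh, kw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, ho * kh, wo * kw, c)
        )
        return dx


class GlobalAvgPool:
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        b, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape).astype(F32) / F32(h * w)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.w = Param(w, "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Dropout:
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def forward(self, x, train: bool, rng):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = F32(1.0 - self.p)
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class ResidualBlock:
    """x + relu(conv(x)); shape preserved by 'same' padding."""

    def __init__(self, channels: int, kernel: tuple[int, int], rng):
        self.conv = Conv2d(channels, channels, kernel, rng)
        self.relu = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return x + self.relu.forward(self.conv.forward(x))

    def backward(self, dy):
        return dy + self.conv.backward(self.relu.backward(dy))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean multiclass cross-entropy and its gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(F32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * np.square(p.grad)
            p.value -= F32(self.lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
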