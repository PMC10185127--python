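"""Minimal numpy neural-network layers with hand-written backprop.

Single-sample (batch of one) 3D tensors of shape (C, D, H, W), float32.
Only the pieces needed for an encoder-decoder segmentation network:
3x3x3 / 1x1x1 convolutions, batch normalization, ReLU, 2x max-pool,
2x transposed convolution, sigmoid, and an Adam optimizer.
"""

from __future__ import annotations

from itertools import product

import numpy as np

F32 = np.float32


class Layer:
    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}


class Conv3x3(Layer):
    """3x3x3 convolution, padding 1 (same shape). Shift-and-GEMM implementation."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 27))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3, 3)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ci, d, h, w = x.shape
        co = self.w.shape[0]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        n = d * h * w
        out = np.zeros((co, n), dtype=F32)
        for a, b, c in product(range(3), repeat=3):
            xs = xp[:, a:a + d, b:b + h, c:c + w].reshape(ci, n)
            out += self.w[:, :, a, b, c] @ xs
        out += self.b[:, None]
        if train:
            self._xp = xp
            self._shape = (d, h, w)
        return out.reshape(co, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d, h, w = self._shape
        ci = self.w.shape[1]
        n = d * h * w
        dyf = dy.reshape(-1, n).astype(F32)
        dxp = np.zeros_like(self._xp)
        for a, b, c in product(range(3), repeat=3):
            xs = self._xp[:, a:a + d, b:b + h, c:c + w].reshape(ci, n)
            self.dw[:, :, a, b, c] += dyf @ xs.T
            dxp[:, a:a + d, b:b + h, c:c + w] += (self.w[:, :, a, b, c].T @ dyf).reshape(ci, d, h, w)
        self.db += dyf.sum(axis=1)
        self._xp = None
        return dxp[:, 1:-1, 1:-1, 1:-1]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class Conv1(Layer):
    """1x1x1 convolution (channel mixing)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, scale, size=(c_out, c_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        ci = x.shape[0]
        xf = x.reshape(ci, -1)
        if train:
            self._xf = xf
            self._shape = x.shape[1:]
        return (self.w @ xf + self.b[:, None]).reshape((-1,) + x.shape[1:])

    def backward(self, dy):
        dyf = dy.reshape(dy.shape[0], -1).astype(F32)
        self.dw += dyf @ self._xf.T
        self.db += dyf.sum(axis=1)
        dx = (self.w.T @ dyf).reshape((-1,) + self._shape)
        self._xf = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class BatchNorm(Layer):
    """Per-channel normalization over the spatial dims (batch of one)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        c = x.shape[0]
        xf = x.reshape(c, -1)
        if train:
            mu = xf.mean(axis=1)
            var = xf.var(axis=1)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mu[:, None]) * inv[:, None]
        if train:
            self._xhat = xhat.astype(F32)
            self._inv = inv.astype(F32)
            self._shape = x.shape
        return (self.gamma[:, None] * xhat + self.beta[:, None]).reshape(x.shape).astype(F32)

    def backward(self, dy):
        c = dy.shape[0]
        dyf = dy.reshape(c, -1).astype(F32)
        self.dgamma += (dyf * self._xhat).sum(axis=1)
        self.dbeta += dyf.sum(axis=1)
        m1 = dyf.mean(axis=1, keepdims=True)
        m2 = (dyf * self._xhat).mean(axis=1, keepdims=True)
        dx = self.gamma[:, None] * self._inv[:, None] * (dyf - m1 - self._xhat * m2)
        self._xhat = None
        return dx.reshape(self._shape)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"run_mean": self.run_mean, "run_var": self.run_var}


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x, train=True):
        c, d, h, w = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (c, d, h, w)
        return out

    def backward(self, dy):
        c, d, h, w = self._shape
        buf = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=F32)
        np.put_along_axis(buf, self._idx[..., None], dy[..., None].astype(F32), axis=-1)
        buf = buf.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        self._idx = None
        return buf.reshape(c, d, h, w)


class UpConv2(Layer):
    """2x2x2 transposed convolution, stride 2 (doubles each spatial dim)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, scale, size=(c_in, c_out, 2, 2, 2)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        ci, d, h, w = x.shape
        co = self.w.shape[1]
        xf = x.reshape(ci, -1)
        out = np.empty((co, 2 * d, 2 * h, 2 * w), dtype=F32)
        for a, b, c in product(range(2), repeat=3):
            out[:, a::2, b::2, c::2] = (self.w[:, :, a, b, c].T @ xf).reshape(co, d, h, w)
        out += self.b[:, None, None, None]
        if train:
            self._xf = xf
            self._shape = (d, h, w)
        return out

    def backward(self, dy):
        d, h, w = self._shape
        ci = self.w.shape[0]
        dx = np.zeros((ci, d * h * w), dtype=F32)
        for a, b, c in product(range(2), repeat=3):
            dyo = dy[:, a::2, b::2, c::2].reshape(dy.shape[0], -1).astype(F32)
            self.dw[:, :, a, b, c] += self._xf @ dyo.T
            dx += self.w[:, :, a, b, c] @ dyo
        self.db += dy.sum(axis=(1, 2, 3))
        self._xf = None
        return dx.reshape(ci, d, h, w)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, pairs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = pairs
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for _, g in self.pairs:
            g[...] = 0
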