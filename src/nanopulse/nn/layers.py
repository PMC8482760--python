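"""Minimal float32 neural-network layers on numpy with manual backprop.

Convolutions are lowered to BLAS matmuls through an im2col view; every layer
caches what its backward pass needs on forward and accumulates parameter
gradients into ``Param.grad``. There is no autodiff graph — the network
classes wire forward and backward explicitly.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Module:
    def params(self) -> list[Param]:
        return []


def _im2col(xp: np.ndarray, k: int, stride: int, l_out: int) -> np.ndarray:
    n, c, _ = xp.shape
    cols = np.empty((n, c, k, l_out), dtype=xp.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, :, j:j + stride * l_out:stride]
    return cols


def _col2im_add(dcols: np.ndarray, lp: int, stride: int) -> np.ndarray:
    n, c, k, l_out = dcols.shape
    dxp = np.zeros((n, c, lp), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, :, j:j + stride * l_out:stride] += dcols[:, :, j, :]
    return dxp


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * kernel))
        self.w = Param(f"{name}.w",
                       rng.standard_normal((c_out, c_in, kernel)) * std)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        else:
            xp = x
        l_out = (xp.shape[2] - self.kernel) // self.stride + 1
        cols = _im2col(xp, self.kernel, self.stride, l_out)
        cols = cols.reshape(x.shape[0], self.c_in * self.kernel, l_out)
        y = np.matmul(self.w.data.reshape(self.c_out, -1), cols)
        self._cache = (cols, xp.shape[2])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, lp = self._cache
        n, _, l_out = dy.shape
        self.w.grad += np.tensordot(dy, cols, axes=([0, 2], [0, 2])).reshape(
            self.w.data.shape)
        dcols = np.matmul(self.w.data.reshape(self.c_out, -1).T, dy)
        dcols = dcols.reshape(n, self.c_in, self.kernel, l_out)
        dxp = _col2im_add(dcols, lp, self.stride)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad]
        return dxp

    def params(self):
        return [self.w]


class GroupNorm(Module):
    """Per-sample normalization over channel groups; identical in train and
    eval mode, which makes inference deterministic."""

    eps = 1e-5

    def __init__(self, groups: int, channels: int, name: str = "gn"):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, l = x.shape
        g = x.reshape(n, self.groups, -1)
        mu = g.mean(axis=2, keepdims=True)
        var = g.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((g - mu) * inv).reshape(n, c, l)
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, l = dy.shape
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        dxh = (dy * self.gamma.data[None, :, None]).reshape(n, self.groups, -1)
        xh = xhat.reshape(n, self.groups, -1)
        m1 = dxh.mean(axis=2, keepdims=True)
        m2 = (dxh * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxh - m1 - xh * m2)
        return dx.reshape(n, c, l)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)),
                    constant_values=-np.inf) if self.pad else x
        l_out = (xp.shape[2] - self.kernel) // self.stride + 1
        cols = _im2col(xp, self.kernel, self.stride, l_out)
        self._arg = cols.argmax(axis=2)
        self._lp = xp.shape[2]
        return cols.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, l_out = dy.shape
        dcols = np.zeros((n, c, self.kernel, l_out), dtype=dy.dtype)
        for j in range(self.kernel):
            dcols[:, :, j, :] = dy * (self._arg == j)
        dxp = _col2im_add(dcols, self._lp, self.stride)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad]
        return dxp


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None] / self._l, self._l, axis=2)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / n_in)
        self.w = Param(f"{name}.w", rng.standard_normal((n_out, n_in)) * std)
        self.b = Param(f"{name}.b", np.zeros(n_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data

    def params(self):
        return [self.w, self.b]


class SGD:
    """Plain SGD with momentum and a settable learning rate."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._buf = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            buf *= self.momentum
            buf += p.grad
            p.data -= self.lr * buf
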