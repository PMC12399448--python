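"""Minimal NumPy neural-network layer stack with manual backpropagation.

Provides exactly the pieces the diffusion denoisers and the desk CNN
classifier need: dense and 3x3 convolution layers (im2col + BLAS matmul),
group normalization, SiLU, nearest-neighbour up/down sampling, sinusoidal
timestep embeddings and an Adam optimizer. Layers cache their forward
activations; ``backward`` consumes the upstream gradient, accumulates
parameter gradients and returns the input gradient.

All randomness flows through an explicit ``numpy.random.Generator`` so that
training runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class Param:
    """One trainable tensor with its gradient and Adam state."""

    __slots__ = ("data", "grad", "m", "v")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.m = np.zeros_like(self.data)
        self.v = np.zeros_like(self.data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.data -= self.lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


class SiLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return silu(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * silu_grad(self._x)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / nin)
        self.W = Param(rng.standard_normal((nin, nout)) * scale)
        self.b = Param(np.zeros(nout))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.data.T


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N,C,H,W) -> (N, C*k*k, Ho*Wo) using k*k shifted views."""
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + Ho * stride : stride,
                                  j : j + Wo * stride : stride]
    return cols.reshape(N, C * k * k, Ho * Wo), (N, C, H, W, Ho, Wo)


def _col2im(gcols: np.ndarray, shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, H, W, Ho, Wo = shape
    g6 = gcols.reshape(N, C, k, k, Ho, Wo)
    gxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=gcols.dtype)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i : i + Ho * stride : stride,
                j : j + Wo * stride : stride] += g6[:, :, i, j]
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp


class Conv2d(Layer):
    """kxk convolution, same padding for stride 1, He-initialized."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1):
        fan_in = cin * k * k
        self.W = Param(rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(cout))
        self.k = k
        self.stride = stride
        self.pad = k // 2

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, shape = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._shape = cols, shape
        N, _, _, _, Ho, Wo = shape
        y = np.einsum("of,nfp->nop", self.W.data, cols, optimize=True)
        return y.reshape(N, -1, Ho, Wo) + self.b.data[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, cout, Ho, Wo = g.shape
        gflat = g.reshape(N, cout, Ho * Wo)
        self.W.grad += np.einsum("nop,nfp->of", gflat, self._cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2, 3))
        gcols = np.einsum("of,nop->nfp", self.W.data, gflat, optimize=True)
        return _col2im(gcols, self._shape, self.k, self.stride, self.pad)


class GroupNorm(Layer):
    """Normalize over (channel-group, H, W) per sample; per-channel affine."""

    def __init__(self, channels: int, groups: int = 1, eps: float = 1e-5):
        assert channels % groups == 0
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.groups = groups
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C = x.shape[:2]
        G = self.groups
        xg = x.reshape(N, G, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (xg - mu) * self._inv
        xhat = self._xhat.reshape(x.shape)
        self._shape = x.shape
        gamma = self.gamma.data.reshape((1, C) + (1,) * (x.ndim - 2))
        beta = self.beta.data.reshape((1, C) + (1,) * (x.ndim - 2))
        self._xhat_full = xhat
        return xhat * gamma + beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C = g.shape[:2]
        G = self.groups
        axes = (0,) + tuple(range(2, g.ndim))
        self.gamma.grad += (g * self._xhat_full).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gamma = self.gamma.data.reshape((1, C) + (1,) * (g.ndim - 2))
        gx_hat = (g * gamma).reshape(N, G, -1)
        xhat = self._xhat
        m = gx_hat.shape[2]
        gxg = (gx_hat - gx_hat.mean(axis=2, keepdims=True)
               - xhat * (gx_hat * xhat).mean(axis=2, keepdims=True)) * self._inv
        return gxg.reshape(self._shape)


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        N, C, H, W = g.shape
        return g.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class AvgPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        g4 = g[:, :, :, None, :, None] / 4.0
        N, C, H, W = self._shape
        return np.broadcast_to(
            g4, (N, C, H // 2, 2, W // 2, 2)
        ).reshape(self._shape)


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard transformer-style sinusoidal embedding of timesteps.

    ``t`` is an integer array of shape (N,); returns (N, dim).
    """
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = np.asarray(t, dtype=float)[:, None] * freqs[None, :]
    return np.concatenate([np.sin(args), np.cos(args)], axis=1)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Integer-label cross entropy; returns (mean loss, dL/dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return float(loss), g / n
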