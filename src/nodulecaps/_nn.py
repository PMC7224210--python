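"""Minimal NumPy neural-network kernel: layers, Adam, and initializers.

Reverse-mode gradients are hand-derived per layer and verified against
central finite differences in the test suite. Convolutions use im2col with
valid padding; all arrays are float64 for deterministic, seedable training
on a single CPU.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix, plus output dims."""
    b, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, ho, wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back onto the input grid."""
    b, c, h, w = x_shape
    dx = np.zeros(x_shape)
    d6 = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += d6[
                :, :, :, :, i, j
            ]
    return dx


class Conv2d:
    """Valid-padding 2D convolution (cross-correlation), stride >= 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        self.W = Param(glorot(rng, (c_out, c_in, kernel, kernel), fan_in, c_out))
        self.b = Param(np.zeros(c_out))
        self.kernel, self.stride = kernel, stride
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_size(self, h: int) -> int:
        return (h - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.kernel, self.stride)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value
        self._cache = (x.shape, cols, ho, wo)
        return y.transpose(0, 2, 1).reshape(x.shape[0], -1, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, ho, wo = self._cache
        b = dy.shape[0]
        dym = dy.reshape(b, -1, ho * wo).transpose(0, 2, 1)  # (B, Ho*Wo, C_out)
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        self.W.grad += np.einsum("bpf,bpc->fc", dym, cols).reshape(self.W.value.shape)
        self.b.grad += dym.sum(axis=(0, 1))
        dcols = dym @ wmat
        return _col2im(dcols, x_shape, self.kernel, self.stride, ho, wo)


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam with bias correction; operates in place on a parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
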