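"""Minimal CPU neural-network layers used by the residual U-Net.

Pure-numpy 2D layers with explicit forward/backward passes: 3x3 and 1x1
convolutions (im2col + matmul), 2x2 max pooling, 2x2 stride-2 transposed
convolution, ReLU, pre-activation residual blocks, and an Adam optimizer.
Everything is float32 and deterministic given a seeded Generator.

The autodiff scope is deliberately narrow: each layer caches what its own
backward pass needs, and models wire layer backwards explicitly in reverse
order. That keeps the code small and the memory profile predictable at the
slice sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ConvTranspose2x2", "MaxPool2x2", "ReLU", "ResidualBlock", "Adam"]

_DT = np.float32


class Layer:
    """Base class: subclasses expose params()/grads() as aligned lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """kxk convolution, stride 1, 'same' zero padding (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H, W, C * k * k)
        self._cols = np.ascontiguousarray(cols, dtype=_DT)
        self._in_shape = x.shape
        Wm = self.W.reshape(self.c_out, -1).T  # (C*k*k, O)
        y = self._cols @ Wm + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, O, H, W = gy.shape
        k, p, C = self.k, self.k // 2, self.c_in
        gy_r = gy.transpose(0, 2, 3, 1).reshape(-1, O).astype(_DT)
        self.gb += gy.sum(axis=(0, 2, 3))
        cols2 = self._cols.reshape(-1, C * k * k)
        self.gW += (cols2.T @ gy_r).T.reshape(self.W.shape)
        Wm = self.W.reshape(O, -1)
        gcols = (gy_r @ Wm).reshape(B, H, W, C, k, k)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=_DT)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + H, j : j + W] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return gxp[:, :, p : p + H, p : p + W] if p else gxp

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * np.sqrt(2.0 / c_in)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        B, C, H, W = x.shape
        y = np.einsum("bchw,coij->bohiwj", x, self.W, optimize=True)
        y = y.reshape(B, self.c_out, 2 * H, 2 * W) + self.b[None, :, None, None]
        return y.astype(_DT)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, O, H2, W2 = gy.shape
        H, W = H2 // 2, W2 // 2
        gy_r = gy.reshape(B, O, H, 2, W, 2)
        self.gb += gy.sum(axis=(0, 2, 3))
        self.gW += np.einsum("bchw,bohiwj->coij", self._x, gy_r, optimize=True)
        gx = np.einsum("bohiwj,coij->bchw", gy_r, self.W, optimize=True)
        self._x = None
        return gx.astype(_DT)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H // 2, W // 2, 4
        )
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        g = np.zeros((B, C, H // 2, W // 2, 4), dtype=_DT)
        np.put_along_axis(g, self._idx[..., None], gy[..., None].astype(_DT), axis=-1)
        g = g.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        self._idx = None
        return g


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


class ResidualBlock(Layer):
    """Pre-activation residual block: ``y = x + conv2(relu(conv1(x)))``.

    Zeroing both convolutions' weights makes the block the exact identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu.forward(self.conv1.forward(x)))
        return x + h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gh = self.conv1.backward(self.relu.backward(self.conv2.backward(gy)))
        return gy + gh

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads()


class Adam:
    """Adam with bias correction over a flat parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grad_refs:
            g[...] = 0.0
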