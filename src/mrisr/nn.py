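"""Minimal NumPy neural-network layers with hand-derived backprop.

Only what the residual super-resolution network needs: 3x3 "same"
convolutions (im2col + matmul), ReLU, 2x pixel shuffle, and an Adam
optimizer over a flat name->array parameter dictionary.  Stride is
always 1 and kernels are always 3x3, which keeps the adjoint of the
convolution a plain correlation with the spatially flipped kernel.

Tensors follow the (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "PixelShuffle2x", "Adam"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) zero-padded by 1 -> (N,H,W,C*9) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * 9)


class Conv2d:
    """3x3 convolution, stride 1, zero padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 9
        bound = 1.0 / np.sqrt(fan_in)
        rng = rng or np.random.default_rng(0)
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in, 3, 3))
        self.b = rng.uniform(-bound, bound, size=(c_out,))
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = _im2col(x)
        if train:
            self._cols = cols
        y = cols @ self.w.reshape(self.c_out, -1).T + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._cols is not None, "forward(train=True) must precede backward"
        n, co, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, co)
        self.gw += (dyf.T @ self._cols.reshape(-1, self.c_in * 9)).reshape(self.w.shape)
        self.gb += dyf.sum(axis=0)
        # dx = full correlation of dy with the flipped kernel, channels swapped
        w_back = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, -1)
        cols_dy = _im2col(np.ascontiguousarray(dy))
        dx = cols_dy @ w_back.T
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dy * self._mask
        self._mask = None
        return dx


class PixelShuffle2x:
    """Rearrange (N, 4C, H, W) -> (N, C, 2H, 2W)."""

    r = 2

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c4, h, w = x.shape
        if c4 % 4:
            raise ValueError("channel count must be divisible by 4")
        c = c4 // 4
        y = x.reshape(n, c, 2, 2, h, w).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(y).reshape(n, c, 2 * h, 2 * w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dx = dy.reshape(n, c, h, 2, w, 2).transpose(0, 1, 3, 5, 2, 4)
        return np.ascontiguousarray(dx).reshape(n, c * 4, h, w)


class Adam:
    """Adam with default moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
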