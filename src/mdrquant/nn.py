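"""Minimal convolutional-network building blocks on numpy.

Implements exactly what the U-Net segmenter needs — 3x3 same-padding
convolution, ReLU, 2x2 max-pooling, nearest-neighbour upsampling, channel
concatenation, 1x1 convolution, softmax cross-entropy (optionally combined
with soft-DICE) and Adam — with hand-written backward passes.

Tensor layout is channels-last ``(N, H, W, C)``: convolutions then lower to
one GEMM per kernel tap on contiguous slices, so BLAS carries the load with
no gather/transpose overhead. Everything is deterministic given the seed on
a single device. Compute dtype is float32 by default; float64 is supported
for gradient checking.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "Conv1x1", "ReLU", "MaxPool2x2", "Upsample2x", "Adam",
           "softmax", "softmax_xent_backward"]


class Conv3x3:
    """3x3 convolution, stride 1, same padding. Weight shape (3, 3, Cin, Cout)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / (c_in * 9))  # He init for ReLU nets
        self.w = (rng.standard_normal((3, 3, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        y = np.empty((n * h * w, self.c_out), dtype=x.dtype)
        y[:] = self.b
        for ky in range(3):
            for kx in range(3):
                sl = np.ascontiguousarray(xp[:, ky:ky + h, kx:kx + w, :]).reshape(-1, c)
                y += sl @ self.w[ky, kx]
        if train:
            self._xp = xp
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward before forward"
        n, h, w, _ = dy.shape
        c = self.c_in
        dy2 = dy.reshape(-1, self.c_out)
        self.dw = np.empty_like(self.w)
        self.db = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for ky in range(3):
            for kx in range(3):
                sl = np.ascontiguousarray(xp[:, ky:ky + h, kx:kx + w, :]).reshape(-1, c)
                self.dw[ky, kx] = sl.T @ dy2
                dxp[:, ky:ky + h, kx:kx + w, :] += (dy2 @ self.w[ky, kx].T).reshape(n, h, w, c)
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("w", self), ("b", self)]


class Conv1x1:
    """Per-pixel linear map across channels. Weight shape (Cin, Cout)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.c_in, self.c_out = c_in, c_out
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = x.reshape(-1, self.c_in) @ self.w + self.b
        if train:
            self._x = x
        return y.reshape(x.shape[:3] + (self.c_out,))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        x2 = x.reshape(-1, self.c_in)
        dy2 = dy.reshape(-1, self.c_out)
        self.dw = x2.T @ dy2
        self.db = dy2.sum(axis=0)
        self._x = None
        return (dy2 @ self.w.T).reshape(x.shape)

    def params(self):
        return [("w", self), ("b", self)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class MaxPool2x2:
    """2x2 max pooling, stride 2. Ties route the gradient to the first
    (row-major) maximal element, keeping backward deterministic."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        if train:
            self._idx = xr.argmax(axis=3)
            self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        out = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        out = out.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(out).reshape(n, h, w, c)

    def params(self):
        return []


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return []


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent_backward(probs: np.ndarray, onehot: np.ndarray, n_pix: int) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. logits given softmax probs."""
    return (probs - onehot) / n_pix


class Adam:
    """Adam over an explicit parameter list ``[(attr_name, layer), ...]``."""

    def __init__(self, params, lr: float = 3e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in self.params]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (name, layer) in enumerate(self.params):
            g = getattr(layer, "d" + name)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p = getattr(layer, name)
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
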