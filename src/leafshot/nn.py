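"""Compact NumPy neural-network engine.

Implements exactly the layer types the backbone needs — 3x3 stride-1
same-padding convolution, 2x2/stride-2 max pooling, global average pooling
and dense layers — together with manual backpropagation and an Adam
optimizer.  Convolutions are lowered to BLAS matrix products via im2col
(``numpy.lib.stride_tricks.sliding_window_view``); the gradient with respect
to the convolution input is computed as a full correlation with the
spatially rotated, channel-transposed kernel, so it reuses the same im2col
path.

All parameters and activations are float32.  Layers cache what backward
needs only when ``forward(..., train=True)`` is used.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    """Glorot/Xavier uniform initialisation, U(-limit, limit) with limit = sqrt(6/(fan_in+fan_out))."""
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    """He uniform initialisation, U(-limit, limit) with limit = sqrt(6/fan_in).

    Preserves activation variance through ReLU layers; used for the
    convolution stack and the ReLU dense layer at build time.
    """
    limit = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Softmax cross-entropy.

    Returns (mean loss, probabilities, gradient of the mean loss w.r.t. the
    logits).  ``labels`` are integer class ids.
    """
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(DTYPE).tiny
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, p, grad.astype(DTYPE)


class Conv2D:
    """3x3, stride-1, same-padding convolution with optional fused ReLU.

    ``W`` has shape (3, 3, c_in, c_out); ``b`` has shape (c_out,).
    ``grad_input=False`` skips the input gradient (first layer of a net).
    """

    has_params = True

    def __init__(self, W: np.ndarray, b: np.ndarray, relu: bool = True, grad_input: bool = True):
        self.W = np.asarray(W, dtype=DTYPE)
        self.b = np.asarray(b, dtype=DTYPE)
        self.relu = relu
        self.grad_input = grad_input
        self.dW = None
        self.db = None
        self._cols = None
        self._act = None
        self._in_shape = None

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (b, h, w, c, 3, 3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        return cols.reshape(b * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        cols = self._im2col(x)
        z = cols @ self.W.reshape(9 * c, -1)
        z += self.b
        if self.relu:
            np.maximum(z, 0.0, out=z)
        out = z.reshape(b, h, w, -1)
        if train:
            self._cols = cols
            self._act = out
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        b, h, w, c = self._in_shape
        f = self.W.shape[-1]
        if self.relu:
            dout = dout * (self._act > 0)
        dflat = dout.reshape(-1, f)
        self.dW = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        self._cols = None
        self._act = None
        if not self.grad_input:
            return None
        # dL/dx = full correlation of dout with the rotated kernel
        w_rot = self.W[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * f, c)
        cols = self._im2col(dout.reshape(b, h, w, f))
        return (cols @ w_rot).reshape(b, h, w, c)


class MaxPool2x2:
    """2x2 max pooling with stride 2 (halves both spatial dimensions)."""

    has_params = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        xw = np.ascontiguousarray(
            x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        ).reshape(b, h // 2, w // 2, c, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        dxw = np.zeros((b, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(dxw, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dxw.reshape(b, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, h, w, c)
        )


class GlobalAvgPool:
    """Collapses each feature map to its spatial mean: (b,h,w,c) -> (b,c)."""

    has_params = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :], (b, h, w, c)) / (h * w)


class Dense:
    """Fully connected layer, optional fused ReLU. ``W``: (n_in, n_out)."""

    has_params = True

    def __init__(self, W: np.ndarray, b: np.ndarray, relu: bool = False):
        self.W = np.asarray(W, dtype=DTYPE)
        self.b = np.asarray(b, dtype=DTYPE)
        self.relu = relu
        self.dW = None
        self.db = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if self.relu:
            np.maximum(z, 0.0, out=z)
        if train:
            self._in = x
            self._act = z
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._act > 0)
        self.dW = self._in.T @ dout
        self.db = dout.sum(axis=0)
        self._in = None
        self._act = None
        return dout @ self.W.T


class Adam:
    """Adam with the framework-standard defaults lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if getattr(l, "has_params", False)]
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, layer in enumerate(self.layers):
            for pname in ("W", "b"):
                g = getattr(layer, "d" + pname)
                if g is None:
                    continue
                key = (i, pname)
                if key not in self._m:
                    self._m[key] = np.zeros_like(g, dtype=DTYPE)
                    self._v[key] = np.zeros_like(g, dtype=DTYPE)
                m, v = self._m[key], self._v[key]
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * np.square(g)
                p = getattr(layer, pname)
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
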