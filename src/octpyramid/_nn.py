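"""Minimal NumPy neural-network primitives.

This module provides exactly what the scale-adaptation autoencoder and the
dense backbone need and nothing more: backprop-capable stride-1 convolutions
(1x1 and kxk "same"), a stride-1 transposed convolution, 2x2 max pooling with
gradient routing, forward-only strided convolution/pooling for the backbone
stem, inference-mode batch normalisation, bilinear resizing expressed as a
pair of linear operators (so its transpose is the exact gradient), global
average pooling, and an Adam optimizer.

Conventions: arrays are NCHW ``float32``; every layer draws its initial
weights from a caller-supplied :class:`numpy.random.Generator` so a single
seed makes a whole network reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; layers are callable on NCHW arrays."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError("layer does not support backprop")

    __call__ = forward


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape).astype(DTYPE) * np.sqrt(2.0 / fan_in).astype(DTYPE)


def _windows(x: np.ndarray, k: int, stride: int, pad: int, fill: float = 0.0) -> np.ndarray:
    """Sliding kxk windows of padded x: (N, C, Ho, Wo, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=fill)
    w = sliding_window_view(x, (k, k), axis=(2, 3))
    if stride > 1:
        w = w[:, :, ::stride, ::stride]
    return w


class Conv2d(Layer):
    """kxk convolution. Backward supported for stride 1 only.

    ``pad=None`` means "same" padding (k//2), the only mode the autoencoder
    uses; the backbone stem uses explicit padding with stride 2 forward-only.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, name: str = "conv"):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        fan_in = c_in * k * k
        self.w = Param(he_init(rng, (c_out, c_in, k, k), fan_in), name + ".w")
        self.b = Param(np.zeros(c_out, dtype=DTYPE), name + ".b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if self.k == 1 and self.stride == 1:
            # fast path: pure channel mixing as one matmul
            n, c, h, wd = x.shape
            y = np.tensordot(self.w.value[:, :, 0, 0], x.reshape(n, c, h * wd), axes=([1], [1]))
            y = y.transpose(1, 0, 2).reshape(n, -1, h, wd) + self.b.value[None, :, None, None]
            self._cache = x
            return y
        win = _windows(x, self.k, self.stride, self.pad)
        y = np.tensordot(win, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]
        self._cache = (x, win)
        return y

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.stride != 1:
            raise NotImplementedError("backward requires stride 1")
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        if self.k == 1:
            x = self._cache
            n, c, h, wd = x.shape
            g2 = gy.reshape(n, -1, h * wd)
            x2 = x.reshape(n, c, h * wd)
            self.w.grad[:, :, 0, 0] += np.einsum("nop,ncp->oc", g2, x2, optimize=True)
            gx = np.tensordot(self.w.value[:, :, 0, 0], g2, axes=([0], [1]))
            return np.ascontiguousarray(gx.transpose(1, 0, 2).reshape(x.shape))
        x, win = self._cache
        # dW: correlate stored windows with the output gradient
        self.w.grad += np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))
        # dX: full correlation of gy with the spatially flipped kernel
        gwin = _windows(gy, self.k, 1, self.k - 1 - self.pad)
        wf = self.w.value[:, :, ::-1, ::-1]
        gx = np.tensordot(gwin, wf, axes=([1, 4, 5], [0, 2, 3]))
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class ConvTranspose2d(Layer):
    """Stride-1 transposed kxk convolution ("same" geometry).

    A stride-1 transposed convolution with padding p is the correlation with
    the spatially flipped kernel at padding k-1-p; with k odd and p=k//2 the
    spatial size is unchanged. Stored kernel shape is (c_in, c_out, k, k) as
    in the usual transposed-conv parameterisation.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 name: str = "tconv"):
        self.k = k
        self.pad = k // 2
        self.w = Param(he_init(rng, (c_in, c_out, k, k), c_in * k * k), name + ".w")
        self.b = Param(np.zeros(c_out, dtype=DTYPE), name + ".b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _as_conv_kernel(self) -> np.ndarray:
        return self.w.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        win = _windows(x, self.k, 1, self.k - 1 - self.pad)
        y = np.tensordot(win, self._as_conv_kernel(), axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]
        self._cache = (x, win)
        return y

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        x, win = self._cache
        gk = np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))  # (c_out, c_in, k, k)
        self.w.grad += gk.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gwin = _windows(gy, self.k, 1, self.pad)
        gx = np.tensordot(gwin, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0).astype(DTYPE)


class MaxPool2x2(Layer):
    """2x2/stride-2 max pooling; trailing odd row/column dropped (floor)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        r = x[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(n, c, ho, wo, 4)
        idx = r.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        n, c, h, w = shape
        ho, wo = h // 2, w // 2
        g = np.zeros((n, c, ho, wo, 4), dtype=DTYPE)
        np.put_along_axis(g, idx[..., None], gy[..., None].astype(DTYPE), axis=-1)
        g = g.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        out = np.zeros(shape, dtype=DTYPE)
        out[:, :, : ho * 2, : wo * 2] = g
        return out


def max_pool(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Forward-only generic max pooling (backbone stem)."""
    win = _windows(x, k, stride, pad, fill=-np.inf)
    return win.max(axis=(4, 5))


class AvgPool(Layer):
    """kxk/stride-k average pooling, floor division on odd sizes."""

    def __init__(self, k: int):
        self.k = k
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        self._shape = x.shape
        return x[:, :, : ho * k, : wo * k].reshape(n, c, ho, k, wo, k).mean(axis=(3, 5))

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k = self.k
        out = np.zeros(self._shape, dtype=DTYPE)
        g = np.repeat(np.repeat(gy, k, axis=2), k, axis=3) / (k * k)
        out[:, :, : g.shape[2], : g.shape[3]] = g
        return out


class BatchNorm2d(Layer):
    """Inference-mode batch normalisation using running statistics.

    Freshly built networks carry running mean 0 / variance 1, so the layer is
    an affine map until pretrained statistics are loaded. eps = 1e-5.
    """

    EPS = 1e-5

    def __init__(self, c: int, name: str = "bn"):
        self.gamma = Param(np.ones(c, dtype=DTYPE), name + ".gamma")
        self.beta = Param(np.zeros(c, dtype=DTYPE), name + ".beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        scale = self.gamma.value / np.sqrt(self.running_var + self.EPS)
        shift = self.beta.value - self.running_mean * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    __call__ = forward


def bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation operator (n_out x n_in).

    Half-pixel-centre convention; applying it along each axis reproduces
    standard bilinear resizing, and its transpose is the exact gradient.
    """
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        a = min(max(i0, 0), n_in - 1)
        b = min(max(i0 + 1, 0), n_in - 1)
        m[i, a] += 1.0 - t
        m[i, b] += t
    return m


class BilinearResize(Layer):
    """Resize NCHW to a fixed (h_out, w_out) via separable linear operators."""

    def __init__(self, h_out: int, w_out: int):
        self.h_out, self.w_out = h_out, w_out
        self._ops: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._in_shape = None

    def _mats(self, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
        key = (h, w)
        if key not in self._ops:
            self._ops[key] = (bilinear_matrix(self.h_out, h), bilinear_matrix(self.w_out, w))
        return self._ops[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        mh, mw = self._mats(x.shape[2], x.shape[3])
        return np.matmul(np.matmul(mh, x), mw.T)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mh, mw = self._mats(self._in_shape[2], self._in_shape[3])
        return np.ascontiguousarray(np.matmul(np.matmul(mh.T, gy), mw))


class Adam:
    """Standard Adam (Kingma & Ba) over a list of Params."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        if self.lr == 0.0:
            return
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad * p.grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
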