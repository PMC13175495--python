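"""Minimal convolutional network engine (forward/backward/Adam) in numpy.

The conditional-GAN generator and discriminator are small enough that an
explicit layer-by-layer implementation with hand-written gradients is both
tractable and fully deterministic on one CPU.  Every layer exposes
``forward(x, train)`` and ``backward(grad_out) -> grad_in``; parameter
gradients accumulate on :class:`Param` objects and are applied by
:class:`Adam`.  All tensors are ``float32`` with layout ``(N, C, H, W)``.

Gradient correctness of each layer is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor with its accumulated gradient and Adam state."""

    __slots__ = ("data", "grad", "m", "v")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.m = np.zeros_like(self.data)
        self.v = np.zeros_like(self.data)


class Layer:
    """Base class; layers without parameters return an empty list."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,Ho,Wo,k,k) view of sliding windows."""
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return windows[:, :, ::stride, ::stride]


def _col2im(cols: np.ndarray, shape: tuple, k: int, stride: int) -> np.ndarray:
    """Scatter-add (N,C,Ho,Wo,k,k) windows back onto a (N,C,Hp,Wp) grid."""
    out = np.zeros(shape, dtype=DTYPE)
    _, _, ho, wo, _, _ = cols.shape
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += cols[:, :, :, :, i, j]
    return out


class Conv2d(Layer):
    """k x k convolution, 'same'-family padding, optional stride."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(rng.normal(0.0, init_std, (cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, self.k, self.stride)
        self._cols = cols
        self._xshape = x.shape
        out = np.einsum("nchwij,ocij->nohw", cols, self.w.data, optimize=True)
        return (out + self.b.data[None, :, None, None]).astype(DTYPE)

    def backward(self, grad):
        self.w.grad += np.einsum("nohw,nchwij->ocij", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        gcols = np.einsum("nohw,ocij->nchwij", grad, self.w.data, optimize=True)
        n, c, h, w = self._xshape
        p = self.pad
        gxp = _col2im(gcols, (n, c, h + 2 * p, w + 2 * p), self.k, self.stride)
        return gxp[:, :, p : p + h, p : p + w] if p else gxp


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution; with k=4, s=2, pad=1 doubles H and W."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(rng.normal(0.0, init_std, (cin, cout, k, k)))
        self.b = Param(np.zeros(cout))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, train=True):
        self._x = x
        n, cin, h, w = x.shape
        cols = np.einsum("nchw,coij->nohwij", x, self.w.data, optimize=True)
        ho, wo = self.out_size(h), self.out_size(w)
        p = self.pad
        full = _col2im(cols, (n, self.w.data.shape[1], ho + 2 * p, wo + 2 * p),
                       self.k, self.stride)
        out = full[:, :, p : p + ho, p : p + wo] if p else full
        return (out + self.b.data[None, :, None, None]).astype(DTYPE)

    def backward(self, grad):
        p = self.pad
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p))) if p else grad
        gcols = _im2col(gp, self.k, self.stride)  # (N,Cout,H,W,k,k)
        self.w.grad += np.einsum("nchw,nohwij->coij", self._x, gcols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        return np.einsum("nohwij,coij->nchw", gcols, self.w.data, optimize=True).astype(DTYPE)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(DTYPE)

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        gm = g.mean(axis=(2, 3), keepdims=True)
        gxm = (g * xhat).mean(axis=(2, 3), keepdims=True)
        return ((g - gm - xhat * gxm) * inv).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad).astype(DTYPE)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y.astype(DTYPE)

    def backward(self, grad):
        return (grad * (1.0 - self._y ** 2)).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False (inference)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x, train=True):
        if not train or self.rate <= 0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return (x * self._mask).astype(DTYPE)

    def backward(self, grad):
        return (grad * self._mask).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam with the bias-corrected update of Kingma & Ba."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v[...] = self.b2 * p.v + (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores; returns (loss, dloss/dlogits).

    ``target`` is the scalar label (1.0 real / 0.0 fake) broadcast over the
    score map.  Uses the softplus form, stable for large |logits|.
    """
    x = logits.astype(np.float64)
    loss = np.mean(np.logaddexp(0.0, x) - target * x)
    sig = 1.0 / (1.0 + np.exp(-x))
    grad = ((sig - target) / x.size).astype(DTYPE)
    return float(loss), grad
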