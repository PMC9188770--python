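"""Minimal CNN layer library (numpy, explicit backprop).

Implements exactly the pieces the image-to-image translator needs:
strided convolution and transposed convolution (im2col / col2im with
BLAS matmuls), batch normalization, dropout, LeakyReLU / ReLU / tanh,
binary cross-entropy on logits, and Adam. Layers are stateless across
calls: ``forward`` returns ``(output, cache)`` and ``backward`` consumes
that cache, so a model can run several forwards before backprop (the GAN
training step forwards the discriminator three times per batch).

All tensors are float32 in NCHW layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

F32 = np.float32


@dataclass
class Mode:
    """Per-call behavior switches.

    ``batch_stats``: batch norm uses batch statistics (and updates
    running averages) instead of running averages.
    ``dropout``: dropout layers are active, drawing from ``rng``.
    """

    batch_stats: bool = False
    dropout: bool = False
    rng: np.random.Generator | None = None


TRAIN = Mode(batch_stats=True, dropout=True)
EVAL = Mode(batch_stats=False, dropout=False)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


# ---------------------------------------------------------------------------
# convolution primitives


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _windows(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """Strided sliding windows: (N, C, Ho, Wo, k, k), a view."""
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::s, ::s]


def conv_out_size(size: int, k: int, s: int, p: int) -> int:
    return (size + 2 * p - k) // s + 1


def _conv_fwd(x, W, s, p):
    """y[n,o] = sum_c W[o,c] * x[n,c]; returns (N, Co, Ho, Wo)."""
    k = W.shape[2]
    win = _windows(_pad(x, p), k, s)
    y = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))  # (N,Ho,Wo,Co)
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


def _conv_bwd_weight(dy, x, k, s, p):
    win = _windows(_pad(x, p), k, s)
    # dW[o,c,i,j] = sum_{n,ho,wo} dy[n,o,ho,wo] * win[n,c,ho,wo,i,j]
    return np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))


def _conv_bwd_data(dy, W, H, Wd, s, p):
    """Adjoint of _conv_fwd back to an input of spatial size (H, Wd)."""
    N = dy.shape[0]
    Ci, k = W.shape[1], W.shape[2]
    Ho, Wo = dy.shape[2], dy.shape[3]
    t = np.tensordot(dy, W, axes=([1], [0]))  # (N,Ho,Wo,Ci,k,k)
    t = t.transpose(0, 3, 1, 2, 4, 5)  # (N,Ci,Ho,Wo,k,k)
    xp = np.zeros((N, Ci, H + 2 * p, Wd + 2 * p), dtype=F32)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += t[:, :, :, :, i, j]
    if p:
        return xp[:, :, p:-p, p:-p]
    return xp


# ---------------------------------------------------------------------------
# layers


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, mode: Mode):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy, cache):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, k=4, stride=2, pad=1, *, init, bias=True):
        self.k, self.s, self.p = k, stride, pad
        mean, sd, rng = init
        self.W = Param(rng.normal(mean, sd, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, mode):
        y = _conv_fwd(x, self.W.value, self.s, self.p)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y, x

    def backward(self, dy, x):
        dy = np.ascontiguousarray(dy, dtype=F32)
        self.W.grad += _conv_bwd_weight(dy, x, self.k, self.s, self.p)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        return _conv_bwd_data(dy, self.W.value, x.shape[2], x.shape[3], self.s, self.p)


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution: the adjoint of Conv2d.

    Weight shape (cin, cout, k, k); output spatial size
    ``(H - 1) * s - 2p + k``.
    """

    def __init__(self, cin, cout, k=4, stride=2, pad=1, *, init, bias=True):
        self.k, self.s, self.p = k, stride, pad
        mean, sd, rng = init
        self.W = Param(rng.normal(mean, sd, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_size(self, size: int) -> int:
        return (size - 1) * self.s - 2 * self.p + self.k

    def forward(self, x, mode):
        H, Wd = self.out_size(x.shape[2]), self.out_size(x.shape[3])
        y = _conv_bwd_data(x, self.W.value, H, Wd, self.s, self.p)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        return y, x

    def backward(self, dy, x):
        dy = np.ascontiguousarray(dy, dtype=F32)
        # roles swap relative to Conv2d: x plays the conv's dy.
        self.W.grad += _conv_bwd_weight(x, dy, self.k, self.s, self.p)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        return _conv_fwd(dy, self.W.value, self.s, self.p)


class BatchNorm2d(Layer):
    def __init__(self, c, *, init, eps=1e-5, momentum=0.1):
        mean, sd, rng = init
        # scale drawn around 1 with the same spread as conv weights
        self.gamma = Param(rng.normal(1.0 + mean, sd, size=c))
        self.beta = Param(np.zeros(c))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, mode):
        if mode.batch_stats:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]
        return y.astype(F32), (xhat, inv, mode.batch_stats)

    def backward(self, dy, cache):
        xhat, inv, batch = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not batch:
            return (dy * g).astype(F32)
        dxhat = dy * self.gamma.value[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(F32)


class Dropout(Layer):
    def __init__(self, p=0.5):
        self.p = p

    def forward(self, x, mode):
        if not mode.dropout or self.p == 0.0:
            return x, None
        rng = mode.rng if mode.rng is not None else np.random.default_rng()
        mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * mask, mask

    def backward(self, dy, mask):
        return dy if mask is None else dy * mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, mode):
        neg = x < 0
        y = np.where(neg, self.alpha * x, x).astype(F32)
        return y, neg

    def backward(self, dy, neg):
        return np.where(neg, self.alpha * dy, dy).astype(F32)


class ReLU(Layer):
    def forward(self, x, mode):
        neg = x < 0
        return np.where(neg, 0.0, x).astype(F32), neg

    def backward(self, dy, neg):
        return np.where(neg, 0.0, dy).astype(F32)


class Tanh(Layer):
    def forward(self, x, mode):
        y = np.tanh(x).astype(F32)
        return y, y

    def backward(self, dy, y):
        return (dy * (1.0 - y * y)).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, mode):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, mode)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(dy, c)
        return dy


# ---------------------------------------------------------------------------
# losses (all on logits, mean reduction)


def bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Stable binary cross-entropy against a constant target in {0, 1}.

    Returns (mean loss, gradient w.r.t. z).
    """
    z = np.asarray(z, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * target + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = (sig - target) / z.size
    return float(loss.mean()), grad.astype(F32)


def l1_loss(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient w.r.t. ``a``."""
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return float(np.abs(d).mean()), (np.sign(d) / d.size).astype(F32)


# ---------------------------------------------------------------------------
# optimizer


@dataclass
class Adam:
    params: list[Param]
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
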