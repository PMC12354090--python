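"""Minimal feed-forward layer framework with explicit reverse-mode gradients.

All trainable components in this package (the GSURE denoiser, the EDM-style
score network and the MoDL regularizer) are small convolutional networks
operating on batches of real-valued channel images shaped ``(B, C, H, W)``.
Layers are purely functional: ``forward`` returns the output together with a
cache, and ``backward`` consumes that cache plus the upstream gradient and
returns the input gradient and per-parameter gradients.  This keeps multiple
concurrent forward passes (needed by Monte-Carlo divergence probing and by
unrolled architectures) trivially correct.

Everything is float64 for deterministic, well-conditioned small-scale
training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "Sequential",
    "Residual",
    "Adam",
    "init_conv_net",
]


class Layer:
    """Base class: stateless apart from the parameter arrays in ``params``."""

    params: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, gy: np.ndarray):  # -> (gx, [gparam, ...])
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        y, _ = self.forward(x)
        return y


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, *,
                 rng: np.random.Generator, zero_init: bool = False) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize * ksize
        if zero_init:
            w = np.zeros((c_out, fan_in))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        b = np.zeros(c_out)
        self.params = [w, b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, H*W, C*k*k)
        B, C, H, W = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)

    def forward(self, x: np.ndarray):
        w, b = self.params
        cols = self._im2col(x)
        y = cols @ w.T + b
        B, C, H, W = x.shape
        y = y.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)
        return y, (cols, x.shape)

    def backward(self, cache, gy: np.ndarray):
        w, _ = self.params
        cols, xshape = cache
        B, C, H, W = xshape
        g = gy.transpose(0, 2, 3, 1).reshape(B, H * W, self.c_out)
        gw = np.einsum("bnc,bnk->ck", g, cols)
        gb = g.sum(axis=(0, 1))
        gcols = g @ w  # (B, H*W, C*k*k)
        gx = self._col2im(gcols, xshape)
        return gx, [gw, gb]

    def _col2im(self, gcols: np.ndarray, xshape) -> np.ndarray:
        B, C, H, W = xshape
        k, p = self.k, self.k // 2
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        g = gcols.reshape(B, H, W, C, k, k)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di:di + H, dj:dj + W] += g[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gxp[:, :, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, gy: np.ndarray):
        return gy * cache, []


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)
        self.params = [p for lay in self.layers for p in lay.params]

    def _sync(self) -> None:
        self.params = [p for lay in self.layers for p in lay.params]

    def forward(self, x: np.ndarray):
        caches = []
        for lay in self.layers:
            x, c = lay.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, gy: np.ndarray):
        grads: list[np.ndarray] = []
        for lay, c in zip(reversed(self.layers), reversed(caches)):
            gy, g = lay.backward(c, gy)
            grads = g + grads
        return gy, grads

    def set_params(self, new: list[np.ndarray]) -> None:
        i = 0
        for lay in self.layers:
            for j in range(len(lay.params)):
                lay.params[j] = new[i]
                i += 1
        self._sync()


class Residual(Layer):
    """y = x + f(x); input and output channel counts of ``f`` must match x."""

    def __init__(self, inner: Layer) -> None:
        super().__init__()
        self.inner = inner
        self.params = inner.params

    def forward(self, x: np.ndarray):
        y, c = self.inner.forward(x)
        return x + y, c

    def backward(self, cache, gy: np.ndarray):
        gx, grads = self.inner.backward(cache, gy)
        return gx + gy, grads


class Adam:
    """Adam on a flat parameter list, updating arrays in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def init_conv_net(c_in: int, c_out: int, hidden: int, n_hidden: int,
                  rng: np.random.Generator, *, zero_last: bool = True) -> Sequential:
    """Plain conv-ReLU stack; zero-initialised last layer gives a zero map."""
    layers: list[Layer] = [Conv2d(c_in, hidden, rng=rng), ReLU()]
    for _ in range(max(0, n_hidden - 1)):
        layers += [Conv2d(hidden, hidden, rng=rng), ReLU()]
    layers.append(Conv2d(hidden, c_out, rng=rng, zero_init=zero_last))
    return Sequential(*layers)
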