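"""Minimal CNN engine: layers, backprop, and Adam, in pure numpy.

The binding model is small (a 17 x 4 x 1 input, three conv blocks, two
dense layers), so a compact, fully deterministic numpy implementation is
both fast enough on a CPU and exactly reproducible across runs.  Layer
semantics (SAME padding for stride-s convolutions, SAME-padded max
pooling) follow the conventions of mainstream deep-learning frameworks so
the architecture reads the same way practitioners expect.

All tensors are NHWC: (batch, height, width, channels). Gradients are
exact (verified against numerical differentiation in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "LeakyReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
]

DTYPE = np.float32


def _same_pad(size: int, stride: int, kernel: int) -> tuple[int, int, int]:
    """SAME-padding arithmetic: output size and (before, after) padding."""
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


class Layer:
    """Base layer: forward caches whatever backward needs."""

    trainable = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """2-D convolution, SAME padding, arbitrary stride.

    Weights: (kh, kw, c_in, c_out), bias: (c_out,). He-normal init scaled
    for leaky-ReLU activations.
    """

    trainable = True

    def __init__(self, c_in: int, c_out: int, kernel=(3, 3), stride=(2, 2),
                 rng: np.random.Generator | None = None, leaky_slope: float = 0.2):
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        fan_in = kh * kw * c_in
        gain = np.sqrt(2.0 / (1.0 + leaky_slope**2))
        self.w = (rng.standard_normal((kh, kw, c_in, c_out)) * gain / np.sqrt(fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.stride = stride
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        kh, kw, _, c_out = self.w.shape
        sh, sw = self.stride
        n, h, w, _ = x.shape
        ho, pt, pb = _same_pad(h, sh, kh)
        wo, pl, pr = _same_pad(w, sw, kw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        if h + pt + pb < (ho - 1) * sh + kh or w + pl + pr < (wo - 1) * sw + kw:
            raise ValueError("input too small for architecture")
        out = np.broadcast_to(self.b, (n, ho, wo, c_out)).copy()
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di : di + sh * ho : sh, dj : dj + sw * wo : sw, :]
                out += np.tensordot(patch, self.w[di, dj], axes=([3], [0]))
        self._cache = (xp, (n, h, w), (pt, pl), (ho, wo))
        return out

    def backward(self, grad):
        xp, (n, h, w), (pt, pl), (ho, wo) = self._cache
        kh, kw, c_in, c_out = self.w.shape
        sh, sw = self.stride
        self.db[...] = grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di : di + sh * ho : sh, dj : dj + sw * wo : sw, :]
                self.dw[di, dj] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + sh * ho : sh, dj : dj + sw * wo : sw, :] += np.tensordot(
                    grad, self.w[di, dj], axes=([3], [1])
                )
        return dxp[:, pt : pt + h, pl : pl + w, :]

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool2D(Layer):
    """Max pooling with SAME padding (padded entries never win the max)."""

    def __init__(self, pool=(2, 2), stride=(1, 1)):
        self.pool = pool
        self.stride = stride

    def forward(self, x, train=True):
        ph, pw = self.pool
        sh, sw = self.stride
        n, h, w, c = x.shape
        ho, pt, pb = _same_pad(h, sh, ph)
        wo, pl, pr = _same_pad(w, sw, pw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
        views = np.stack(
            [
                xp[:, di : di + sh * ho : sh, dj : dj + sw * wo : sw, :]
                for di in range(ph)
                for dj in range(pw)
            ]
        )  # (ph*pw, n, ho, wo, c)
        arg = views.argmax(axis=0)
        out = np.take_along_axis(views, arg[None], axis=0)[0]
        self._cache = (arg, (n, h, w, c), (pt, pl), (ho, wo), xp.shape)
        return out

    def backward(self, grad):
        arg, (n, h, w, c), (pt, pl), (ho, wo), xp_shape = self._cache
        ph, pw = self.pool
        sh, sw = self.stride
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        ii, jj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        for k in range(ph * pw):
            di, dj = divmod(k, pw)
            mask = arg == k
            rows = (ii * sh + di)[None, :, :, None]
            cols = (jj * sw + dj)[None, :, :, None]
            contrib = np.where(mask, grad, 0.0)
            # scatter-add into strided windows; windows can overlap when
            # stride < pool, so accumulate per offset
            np.add.at(
                dxp,
                (
                    np.arange(n)[:, None, None, None],
                    np.broadcast_to(rows, grad.shape),
                    np.broadcast_to(cols, grad.shape),
                    np.arange(c)[None, None, None, :],
                ),
                contrib,
            )
        return dxp[:, pt : pt + h, pl : pl + w, :]


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot-uniform
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]


class Sequential:
    """A plain layer stack with forward/backward and a flat parameter view."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w


class Adam:
    """Adam optimiser over a Sequential's parameter list."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.params]
        self.v = [np.zeros_like(p) for p in net.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.net.params, self.net.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
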