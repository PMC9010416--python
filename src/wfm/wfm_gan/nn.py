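"""Minimal convolutional network core with explicit backpropagation.

Just enough machinery for the translator networks: strided convolutions
via im2col, nearest-neighbour upsampling, instance normalization, the
usual activations, and Adam.  Layers are functional — ``forward`` returns
``(output, tape)`` and ``backward(grad, tape)`` returns the input
gradient while accumulating parameter gradients — so one network can be
replayed through several loss branches per step (the discriminator sees
both the real and the generated pair).

Arrays are float32 NCHW.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """Trainable tensor with gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam with the translator's defaults (lr 2e-4, beta1 0.5, beta2 0.9)."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.9, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, tape):
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.reshape(n, c * k * k, ho * wo)


class Conv2d(Layer):
    """k x k convolution, stride s, zero padding p; He-uniform init."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        bound = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, bound, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)
        out = (
            np.einsum("of,nfp->nop", self.w.value, cols, optimize=True)
            + self.b.value[None, :, None]
        )
        return out.reshape(n, self.cout, ho, wo), (cols, x.shape)

    def backward(self, dy, tape):
        cols, xshape = tape
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        dyf = dy.reshape(n, self.cout, ho * wo)
        self.w.grad += np.einsum("nop,nfp->of", dyf, cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.w.value, dyf, optimize=True)
        dcols = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + ho * s : s, kj : kj + wo * s : s] += dcols[
                    :, :, ki, kj
                ]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Upsample2x(Layer):
    """Nearest-neighbour x2 upsampling (checkerboard-free decoder path)."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3), x.shape

    def backward(self, dy, tape):
        n, c, h, w = tape
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class InstanceNorm(Layer):
    """Per-sample per-channel normalization with affine scale/shift."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy, tape):
        xhat, inv = tape
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        return (
            inv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
            )
        )


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x):
        mask = x > 0
        return np.where(mask, x, self.alpha * x), mask

    def backward(self, dy, mask):
        return np.where(mask, dy, self.alpha * dy)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, mask):
        return dy * mask


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, y):
        return dy * (1.0 - y * y)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y, y

    def backward(self, dy, y):
        return dy * y * (1.0 - y)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        tapes = []
        for l in self.layers:
            x, t = l.forward(x)
            tapes.append(t)
        return x, tapes

    def backward(self, dy, tapes):
        for l, t in zip(reversed(self.layers), reversed(tapes)):
            dy = l.backward(dy, t)
        return dy


def n_parameters(net: Layer) -> int:
    return int(sum(p.value.size for p in net.params()))
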