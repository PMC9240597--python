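"""Minimal feed-forward layer framework with manual backpropagation.

Supports the small architectures used here: dense stacks, 2-D
convolutions and transposed convolutions over single-channel feature
matrices, trained with Adam. All arrays are float64, batch-first.
Convolutions are implemented by gathering kernel-offset slices
(im2col) so forward and backward reduce to matrix products.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Dense", "ReLU", "LeakyReLU", "Sigmoid", "Tanh", "Dropout",
    "Flatten", "Reshape", "Conv2d", "ConvTranspose2d", "Sequential", "Adam",
]


class Layer:
    """Base layer: caches what backward needs during forward."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style fan-in scaling; fine for both ReLU and linear heads here
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.dW[...] = self._x.T @ grad_out
        self.db[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, 0.0)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, self.alpha * grad_out)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, grad_out):
        return grad_out * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad_out):
        return grad_out * (1.0 - self._y ** 2)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Gather kernel-offset slices: (B,C,H,W) -> (B, C*k*k, Ho*Wo)."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - k) // stride + 1
    Wo = (W + 2 * pad - k) // stride + 1
    cols = np.empty((B, C, k, k, Ho, Wo))
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
    return cols.reshape(B, C * k * k, Ho * Wo), (Ho, Wo)


def _col2im(cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int,
            pad: int, out_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of _im2col: scatter-add slices back to (B,C,H,W)."""
    B, C, H, W = x_shape
    Ho, Wo = out_hw
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    cols = cols.reshape(B, C, k, k, Ho, Wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._cols, self._out_hw = _im2col(x, self.k, self.stride, self.pad)
        out = np.einsum("oc,bcp->bop", self.W, self._cols)
        out += self.b[None, :, None]
        B = x.shape[0]
        Ho, Wo = self._out_hw
        return out.reshape(B, self.c_out, Ho, Wo)

    def backward(self, grad_out):
        B = grad_out.shape[0]
        g = grad_out.reshape(B, self.c_out, -1)
        self.dW[...] = np.einsum("bop,bcp->oc", g, self._cols)
        self.db[...] = g.sum(axis=(0, 2))
        dcols = np.einsum("oc,bop->bcp", self.W, g)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad, self._out_hw)


class ConvTranspose2d(Layer):
    """Transposed convolution: the adjoint of Conv2d's forward map.

    Maps (B, c_in, H, W) -> (B, c_out, (H-1)*stride - 2*pad + k, ...).
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        # stored in the same (conv) layout: maps c_out cols back to c_in maps
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out * k * k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def out_hw(self, H: int, W: int) -> tuple[int, int]:
        s, k, p = self.stride, self.k, self.pad
        return ((H - 1) * s - 2 * p + k, (W - 1) * s - 2 * p + k)

    def forward(self, x, train=False):
        B, C, H, W = x.shape
        self._x = x
        Ho, Wo = self.out_hw(H, W)
        self._out_shape = (B, self.c_out, Ho, Wo)
        xf = x.reshape(B, C, H * W)
        cols = np.einsum("cf,bcp->bfp", self.W, xf)  # (B, c_out*k*k, H*W)
        out = _col2im(cols, self._out_shape, self.k, self.stride, self.pad, (H, W))
        return out + self.b[None, :, None, None]

    def backward(self, grad_out):
        B, C, H, W = self._x.shape
        cols, _ = _im2col(grad_out, self.k, self.stride, self.pad)  # (B, c_out*k*k, H*W)
        xf = self._x.reshape(B, C, H * W)
        self.dW[...] = np.einsum("bcp,bfp->cf", xf, cols)
        self.db[...] = grad_out.sum(axis=(0, 2, 3))
        dx = np.einsum("cf,bfp->bcp", self.W, cols)
        return dx.reshape(B, C, H, W)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for l in reversed(self.layers):
            grad_out = l.backward(grad_out)
        return grad_out

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
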