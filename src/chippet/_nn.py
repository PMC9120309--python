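"""Minimal NumPy neural-network layers for the position regressor.

Implements exactly what the CNN estimator needs — im2col convolutions,
ReLU, global average pooling, dense layers, MAE loss and Adam — with
explicit forward/backward passes.  Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "GlobalAvgPool", "Linear", "Sequential", "Adam",
           "mae_loss"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = (hp - kh) // stride + 1, (wp - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    shape = (n, c, kh, kw, ho, wo)
    strides = (
        xp.strides[0], xp.strides[1],
        xp.strides[2], xp.strides[3],
        xp.strides[2] * stride, xp.strides[3] * stride,
    )
    cols = np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)
    return cols.reshape(n, c * kh * kw, ho * wo), (ho, wo, hp, wp)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            (c_out, c_in, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x_shape = x.shape
        cols, (ho, wo, hp, wp) = _im2col(x, self.kernel, self.kernel,
                                         self.stride, self.pad)
        cols = np.ascontiguousarray(cols)
        self._cols, self._hw = cols, (ho, wo, hp, wp)
        wmat = self.w.reshape(len(self.w), -1)
        out = np.matmul(wmat[None], cols) + self.b[None, :, None]
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, grad_out):
        n, c_out, ho, wo = grad_out.shape
        g = np.ascontiguousarray(grad_out.reshape(n, c_out, ho * wo))
        wmat = self.w.reshape(c_out, -1)
        # sum over batch of g @ cols^T, as one flattened matmul
        gw = g.transpose(1, 0, 2).reshape(c_out, -1) @ \
            self._cols.transpose(1, 0, 2).reshape(self._cols.shape[1], -1).T
        self.grads[0][...] = gw.reshape(self.w.shape)
        self.grads[1][...] = g.sum(axis=(0, 2))
        gcols = np.matmul(wmat.T[None], g)
        # col2im
        _, c_in, h, w = self._x_shape
        _, _, hp, wp = self._hw
        k, s = self.kernel, self.stride
        gx = np.zeros((n, c_in, hp, wp), dtype=grad_out.dtype)
        gcols = gcols.reshape(n, c_in, k, k, ho, wo)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, i, j]
        p = self.pad
        return gx[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None] / (h * w),
                               self._shape).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in),
                            (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad_out):
        self.grads[0][...] = self._x.T @ grad_out
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.w.T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = np.abs(diff).mean()
    grad = np.sign(diff) / diff.size
    return loss, grad


class Adam:
    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
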