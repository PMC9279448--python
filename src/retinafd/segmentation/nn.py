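"""Minimal NumPy neural-network layers with explicit backprop.

Self-contained building blocks for the vessel-segmentation network:
3x3/1x1 convolutions with "same" padding (im2col), batch normalization,
ReLU, 2x2 max pooling, 2x nearest-neighbor upsampling, channel
concatenation, and an Adam optimizer.  Tensors are (N, C, H, W) float32.
Deliberately small: only what the encoder-decoder model needs, sized for
CPU training on reduced configurations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same padding (k odd)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        # He initialization for ReLU networks
        std = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        wmat = self.params["W"].reshape(self.cout, -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        # dx = "full" correlation of dout with spatially flipped, transposed W
        wflip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (cin, cout, k, k)
        dcols = _im2col(dout, self.k)
        dx = dcols @ wflip.reshape(self.cin, -1).T
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + \
            self.params["beta"][None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        n, c, h, w = shape
        m = n * h * w
        dxhat = dout * g
        # standard batch-norm backward with batch statistics
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (t1 - t2)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; input sides must be even."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # winner mask; ties share the gradient equally
        winners = xr == out[:, :, :, None, :, None]
        self._cache = (winners, winners.sum(axis=(3, 5), keepdims=True), x.shape)
        return out

    def backward(self, dout):
        winners, counts, shape = self._cache
        d = winners * (dout[:, :, :, None, :, None] / counts)
        n, c, h, w = shape
        return d.reshape(n, c, h, w)


class Upsample2(Layer):
    """2x nearest-neighbor upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over the parameters of a list of layers."""

    def __init__(self, layers, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(np.float32)
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1 ** self.t)
                vhat = v[k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
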