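"""Minimal 1D convolutional network engine in NumPy.

Implements exactly the layer types the compression-quality classifiers need
— same-padded 1D convolution (stride 1), ReLU, batch normalization over
(batch, length), length-2 max pooling with floor division, inverted dropout,
dense layers and a softmax/cross-entropy head — with explicit forward and
backward passes and an Adam optimizer.  Everything is seeded through a
single ``numpy.random.Generator``; there is no global state.

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1d",
    "ReLU",
    "BatchNorm1d",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "conv1d_valid",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def conv1d_valid(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Plain valid-mode 1D correlation: out[j] = sum_k w[k] x[j+k] + b.

    The elementary operation every convolution layer applies per
    channel pair; exposed for direct verification.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    n = len(x) - len(kernel) + 1
    if n < 1:
        raise ValueError("kernel longer than input")
    return np.array([float(x[j : j + len(kernel)] @ kernel) + bias for j in range(n)])


class Layer:
    """Base layer: forward/backward plus named trainable parameters."""

    training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}


class Conv1d(Layer):
    """Same-padded 1D convolution, stride 1, odd kernel length."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng):
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        # (B, C, L, k) -> (B, C*k, L)
        B, C, L, k = win.shape
        return win.transpose(0, 1, 3, 2).reshape(B, C * k, L)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = self._im2col(x)
        out = np.tensordot(self.W, self._cols, axes=([1], [1]))  # (O, B, L)
        return out.transpose(1, 0, 2) + self.b[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = np.tensordot(grad, self._cols, axes=([0, 2], [0, 2]))
        self.db = grad.sum(axis=(0, 2))
        dcols = np.tensordot(grad, self.W, axes=([1], [0])).transpose(0, 2, 1)
        B, C, L = self._in_shape
        k, p = self.kernel, self.kernel // 2
        dxp = np.zeros((B, C, L + 2 * p))
        dcols = dcols.reshape(B, C, k, L)
        for j in range(k):
            dxp[:, :, j : j + L] += dcols[:, :, j, :]
        return dxp[:, :, p : p + L] if p else dxp

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, length) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2))
        self.dbeta = grad.sum(axis=(0, 2))
        if not self.training:
            return grad * self.gamma[None, :, None] / self._std
        B, _, L = grad.shape
        m = B * L
        g = grad * self.gamma[None, :, None]
        s1 = g.sum(axis=(0, 2))[None, :, None]
        s2 = (g * self._xhat).sum(axis=(0, 2))[None, :, None]
        return (g - s1 / m - self._xhat * s2 / m) / self._std

    def parameters(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def gradients(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class MaxPool1d(Layer):
    """Length-2 max pooling; an odd trailing sample is dropped (floor)."""

    def forward(self, x):
        B, C, L = x.shape
        self._in_len = L
        Lp = L // 2
        xt = x[:, :, : 2 * Lp].reshape(B, C, Lp, 2)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, grad):
        B, C, Lp = grad.shape
        dx = np.zeros((B, C, self._in_len))
        dxt = dx[:, :, : 2 * Lp].reshape(B, C, Lp, 2)
        np.put_along_axis(dxt, self._arg[..., None], grad[..., None], axis=3)
        dx[:, :, : 2 * Lp] = dxt.reshape(B, C, 2 * Lp)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.dW = grad.T @ self._x
        self.db = grad.sum(axis=0)
        return grad @ self.W

    def parameters(self):
        return {"W": self.W, "b": self.b}

    def gradients(self):
        return {"W": self.dW, "b": self.db}


class Sequential:
    """Ordered layer container with a training-mode flag."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.training = False

    def train_mode(self, flag: bool = True) -> None:
        self.training = flag
        for layer in self.layers:
            layer.training = flag

    def forward(self, x: np.ndarray, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[int, str, np.ndarray]]:
        return [
            (i, name, arr)
            for i, layer in enumerate(self.layers)
            for name, arr in layer.parameters().items()
        ]

    def gradients(self) -> list[np.ndarray]:
        return [
            layer.gradients()[name]
            for i, layer in enumerate(self.layers)
            for name in layer.parameters()
        ]

    def n_parameters(self) -> int:
        return int(sum(arr.size for _, _, arr in self.parameters()))


class Adam:
    """Adaptive-moment gradient descent on a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = net.parameters()
        self.m = [np.zeros_like(p) for _, _, p in params]
        self.v = [np.zeros_like(p) for _, _, p in params]

    def step(self) -> None:
        self.t += 1
        params = self.net.parameters()
        grads = self.net.gradients()
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for (_, _, p), g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
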