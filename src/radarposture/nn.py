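"""Minimal NumPy neural-network layers for the multiview classifier.

Implements exactly what the posture classifier needs — 3x3 convolutions,
ReLU, 2x2 max pooling, global average pooling, dense layers, residual and
densely-connected blocks, softmax cross-entropy and AdamW — with explicit
forward/backward passes.  Layers cache what their backward pass needs;
``backward`` must be called with the same batch that was last forwarded.

All randomness (weight init, batch shuffling) flows through an explicit
``numpy.random.Generator``, so training is bit-reproducible given a seed
on a fixed BLAS configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "ResidualBlock",
    "DenseBlock",
    "softmax",
    "cross_entropy_with_logits",
    "AdamW",
]


class Layer:
    """Base layer: parameters and their gradients live in dicts."""

    def __init__(self):
        self.params: dict = {}
        self.grads: dict = {}

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def param_items(self):
        """Yield (layer, key) pairs for every trainable array."""
        for k in self.params:
            yield self, k


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, He-normal init."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        fan_in = c_in * k * k
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.params["W"] = rng.standard_normal((c_out, c_in * k * k)) * np.sqrt(2.0 / fan_in)
        self.params["b"] = np.zeros(c_out)
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        y = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        k = self.k
        pad = k // 2
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = g.T @ cols
        self.grads["b"] = g.sum(axis=0)
        dcols = (g @ self.params["W"]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, pad : pad + h, pad : pad + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {(h, w)}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._inshape = x.shape
        return xr.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._inshape
        out = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._argmax[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c) spatial mean."""

    def forward(self, x):
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._inshape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.params["W"] = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.params["b"] = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def param_items(self):
        for layer in self.layers:
            yield from layer.param_items()


class ResidualBlock(Layer):
    """conv-relu-conv with identity skip, ReLU after the sum."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.conv1 = Conv2d(channels, channels, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng)
        self.relu_out = ReLU()

    def forward(self, x):
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + y)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + g_branch

    def param_items(self):
        yield from self.conv1.param_items()
        yield from self.conv2.param_items()


class DenseBlock(Layer):
    """Densely connected block: output = concat(x, conv(relu(x)))."""

    def __init__(self, c_in: int, growth: int, rng=None):
        super().__init__()
        self.c_in = c_in
        self.relu = ReLU()
        self.conv = Conv2d(c_in, growth, rng=rng)

    def forward(self, x):
        y = self.conv.forward(self.relu.forward(x))
        return np.concatenate([x, y], axis=1)

    def backward(self, grad):
        gx = grad[:, : self.c_in]
        gy = grad[:, self.c_in :]
        return gx + self.relu.backward(self.conv.backward(gy))

    def param_items(self):
        yield from self.conv.param_items()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``targets`` are integer class indices.  Returns (loss, dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n


class AdamW(object):
    """Adam with decoupled weight decay.

    Defaults follow the common recipe: lr 1e-3, betas (0.9, 0.999),
    eps 1e-8, weight decay 0.01 (applied to weights, not biases).
    """

    def __init__(self, param_items, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        b1, b2 = betas
        if not (0 < b1 < b2 < 1):
            raise ValueError("betas must satisfy 0 < beta1 < beta2 < 1")
        self.items = list(param_items)
        self.lr, self.b1, self.b2 = lr, b1, b2
        self.eps, self.wd = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in self.items]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in self.items]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (layer, k) in enumerate(self.items):
            g = layer.grads[k]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p = layer.params[k]
            update = mhat / (np.sqrt(vhat) + self.eps)
            if k == "W" and self.wd > 0:
                update = update + self.wd * p
            layer.params[k] = p - self.lr * update
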