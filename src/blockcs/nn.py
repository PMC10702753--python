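"""A compact numpy CNN engine: layers, loss and SGD with momentum.

Supports exactly what the AlexNet-style classifier needs — strided/padded
convolution (im2col), ReLU, max pooling, flatten, fully connected layers,
inverted dropout and softmax cross-entropy — with explicit backprop and
seeded initialization so training is bit-reproducible.

Tensors are NCHW (float32 parameters by default); minibatch gradients are
averaged.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Default parameter dtype; float32 halves memory traffic at CNN scale.
DTYPE = np.float32

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "SGD",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N*oh*ow, C*k*k) patch matrix."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = windows.shape[:4]
    # (N, oh, ow, C, k, k) -> rows of flattened patches
    return (
        windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k),
        oh,
        ow,
    )


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, oh: int, ow: int):
    """Scatter-add patch-matrix gradients back to (N, C, H, W)."""
    n, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=cols.dtype)
    cols = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di : di + oh * stride : stride, dj : dj + ow * stride : stride] += cols[
                :, :, :, :, di, dj
            ]
    return dx


class Layer:
    """Base layer; stateless layers override forward/backward only."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution with He-normal initialization."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=DTYPE) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.w = (
            rng.standard_normal((out_ch, in_ch, kernel, kernel))
            * np.sqrt(2.0 / fan_in)
        ).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.kernel, self.stride)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.w.reshape(self.w.shape[0], -1).T + self.b
        n = x.shape[0]
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, oc, oh, ow = grad.shape
        gcols = grad.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads[0][...] = (gcols.T @ self._cols).reshape(self.w.shape)
        self.grads[1][...] = gcols.sum(axis=0)
        dcols = gcols @ self.w.reshape(oc, -1)
        dx = _col2im(dcols, self._x_shape, self.kernel, self.stride, oh, ow)
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool(Layer):
    """Max pooling with square window and arbitrary stride."""

    def __init__(self, size: int, stride: int | None = None) -> None:
        super().__init__()
        self.size = size
        self.stride = stride or size

    def forward(self, x, train=False, rng=None):
        k, s = self.size, self.stride
        self._x_shape = x.shape
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = windows.shape[:4]
        flat = windows.reshape(n, c, oh, ow, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._out_shape = (n, c, oh, ow)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, oh, ow = self._out_shape
        k, s = self.size, self.stride
        dx = np.zeros(self._x_shape, dtype=grad.dtype)
        if s == k:
            # non-overlapping windows: collision-free scatter
            buf = np.zeros((n, c, oh, ow, k * k), dtype=grad.dtype)
            np.put_along_axis(buf, self._argmax[..., None], grad[..., None], -1)
            dx[:, :, : oh * k, : ow * k] = (
                buf.reshape(n, c, oh, ow, k, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, oh * k, ow * k)
            )
            return dx
        ni, ci, ii, jj = np.indices((n, c, oh, ow))
        rows = ii * s + self._argmax // k
        cols = jj * s + self._argmax % k
        np.add.at(dx, (ni, ci, rows, cols), grad)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None,
                 dtype=DTYPE) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at rate 0 or outside training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((rng.random(x.shape) < keep) / keep).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels`` are integer class indices of shape (N,).
    """
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-300).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads) -> None:
        for p, g, v in zip(self.params, grads, self.velocity, strict=True):
            v *= self.momentum
            v -= self.lr * g
            p += v
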