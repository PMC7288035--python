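"""A small, self-contained convolutional-network engine on numpy.

Implements exactly the pieces the soft sensor needs: same-padded 2D
convolution (im2col + GEMM), ReLU, 2x2 max pooling, flatten, dense layers,
inverted dropout, softmax cross-entropy, and the Adam optimiser.  Arrays are
NHWC float32; every source of randomness (weight init, dropout masks) comes
from an explicit numpy Generator, so runs are deterministic for a fixed
seed.  Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: forward/backward plus flat parameter access."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded stride-1 convolution with a 3x3 (or kxk) kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = kernel * kernel * in_ch
        w = rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)
        self.params = [w.astype(dtype), np.zeros(out_ch, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win: (n, h, w, c, k, k) -> (n, h, w, k, k, c)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        return np.ascontiguousarray(win).reshape(n * h * w, self.k * self.k * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x_shape = x.shape
        n, h, w, _ = x.shape
        self.col = self._im2col(x)
        out = self.col @ self.params[0] + self.params[1]
        return out.reshape(n, h, w, self.out_ch)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        dflat = dout.reshape(-1, self.out_ch)
        self.grads[0][...] = self.col.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcol = (dflat @ self.params[0].T).reshape(n, h, w, self.k, self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + h, j:j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class MaxPool2D(Layer):
    """Non-overlapping pooling; trailing rows/columns that do not fill a
    window are dropped (floor division, as in common framework defaults)."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.p = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.p
        self.x_shape = x.shape
        h2, w2 = h // p, w // p
        xc = x[:, :h2 * p, :w2 * p, :]
        win = xc.reshape(n, h2, p, w2, p, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h2, w2, p * p, c)
        self.argmax = win.argmax(axis=3)
        return np.take_along_axis(win, self.argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self.x_shape
        p = self.p
        h2, w2 = h // p, w // p
        dwin = np.zeros((n, h2, w2, p * p, c), dtype=dout.dtype)
        np.put_along_axis(dwin, self.argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self.x_shape, dtype=dout.dtype)
        dx[:, :h2 * p, :w2 * p, :] = (
            dwin.reshape(n, h2, w2, p, p, c).transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2 * p, w2 * p, c)
        )
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self.x_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.params = [w.astype(dtype), np.zeros(out_dim, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Dropout(Layer):
    """Inverted dropout: active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self.mask is None else dout * self.mask


class Sequential:
    """A plain layer stack emitting class logits."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adaptive-moment-estimation optimiser (standard bias correction)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
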