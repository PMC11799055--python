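"""A small convolutional network implemented on numpy.

Sized for CPU-scale experiments on speckle-statistics images: two 3x3
convolution blocks with ReLU and 2x2 max pooling, one hidden dense layer,
softmax output, trained by mini-batch SGD with momentum and inverted
dropout.  Forward and backward passes are exact (numerically verified
against finite differences in the test suite), so the network is a real,
if compact, CNN rather than an approximation.

Layout convention: activations are (N, C, H, W) float32/float64 arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H_out*W_out) patch matrix for 'valid' conv."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    n, c, ho, wo, _, _ = windows.shape
    return (
        windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo),
        (ho, wo),
    )


class Conv2D:
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols, (ho, wo) = _im2col(xp, self.k)
        out = np.einsum("of,nfp->nop", self.W, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n = x_shape[0]
        d = dout.reshape(n, self.c_out, ho * wo)
        self.dW = np.einsum("nop,nfp->of", d, cols)
        self.db = d.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", self.W, d)
        dcols = dcols.reshape(n, self.c_in, self.k, self.k, ho, wo)
        p = self.k // 2
        dxp = np.zeros((n, self.c_in, x_shape[2] + 2 * p, x_shape[3] + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
        return dxp[:, :, p:p + x_shape[2], p:p + x_shape[3]]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (input H, W assumed even)."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = self._mask * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Two conv blocks + one hidden dense layer + softmax over n_classes."""

    def __init__(
        self,
        input_size: int = 32,
        n_classes: int = 3,
        channels: tuple[int, int] = (8, 16),
        hidden: int = 32,
        dropout: float = 0.25,
        seed: int = 0,
    ):
        if input_size % 4 != 0:
            raise ValueError("input size must be divisible by 4 (two 2x2 pools)")
        rng = np.random.default_rng(seed)
        self.dropout = float(dropout)
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        c1, c2 = channels
        s = input_size // 4
        self.conv1 = Conv2D(3, c1, 3, rng)
        self.conv2 = Conv2D(c1, c2, 3, rng)
        self.fc1 = Dense(c2 * s * s, hidden, rng)
        self.fc2 = Dense(hidden, n_classes, rng)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        self.n_classes = n_classes
        self._rng = rng

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a (N, 3, H, W) batch."""
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        h = self.pool2.forward(self.relu2.forward(self.conv2.forward(h)))
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self._drop(h, train, 0)
        h = self.relu3.forward(self.fc1.forward(h))
        h = self._drop(h, train, 1)
        return softmax(self.fc2.forward(h))

    def _drop(self, h, train, slot):
        if not train or self.dropout == 0:
            if not hasattr(self, "_dmask"):
                self._dmask = [None, None]
            self._dmask[slot] = None
            return h
        if not hasattr(self, "_dmask"):
            self._dmask = [None, None]
        keep = 1.0 - self.dropout
        mask = (self._rng.random(h.shape) < keep) / keep
        self._dmask[slot] = mask
        return h * mask

    # -- training --------------------------------------------------------
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        """Mean cross-entropy and parameter gradients for a labelled batch."""
        n = x.shape[0]
        probs = self.forward(x, train=train)
        loss = float(-np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean())
        dz = probs.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        dh = self.fc2.backward(dz)
        if self._dmask[1] is not None:
            dh = dh * self._dmask[1]
        dh = self.fc1.backward(self.relu3.backward(dh))
        if self._dmask[0] is not None:
            dh = dh * self._dmask[0]
        dh = dh.reshape(self._flat_shape)
        dh = self.conv2.backward(self.relu2.backward(self.pool2.backward(dh)))
        self.conv1.backward(self.relu1.backward(self.pool1.backward(dh)))
        return loss

    def layers(self):
        return {"conv1": self.conv1, "conv2": self.conv2,
                "fc1": self.fc1, "fc2": self.fc2}

    def get_params(self) -> dict:
        return {
            name: {k: v.copy() for k, v in layer.params().items()}
            for name, layer in self.layers().items()
        }

    def set_params(self, params: dict) -> None:
        for name, layer in self.layers().items():
            for k in layer.params():
                layer.params()[k][...] = params[name][k]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i:i + batch_size], train=False))
        return np.concatenate(out, axis=0)


class SGD:
    """Stochastic gradient descent with classical momentum.

    Gradients are rescaled when their global L2 norm exceeds ``clip_norm``;
    without this, occasional large mini-batch gradients can blow the small
    network into a dead all-one-class state it cannot recover from.
    """

    def __init__(self, model: SmallCNN, lr: float, momentum: float = 0.9,
                 clip_norm: float = 1.0):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.v = {
            name: {k: np.zeros_like(v) for k, v in layer.params().items()}
            for name, layer in model.layers().items()
        }

    def step(self) -> None:
        layers = self.model.layers()
        scale = 1.0
        if self.clip_norm is not None:
            total = 0.0
            for layer in layers.values():
                for g in layer.grads().values():
                    total += float((g * g).sum())
            norm = np.sqrt(total)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for name, layer in layers.items():
            grads = layer.grads()
            for k, p in layer.params().items():
                v = self.v[name][k]
                v *= self.momentum
                v -= self.lr * scale * grads[k]
                p += v
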