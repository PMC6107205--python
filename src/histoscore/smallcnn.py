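"""A compact convolutional network with full backpropagation on numpy.

This is the desk-scale classifier backend: three conv-relu-maxpool blocks,
global average pooling and a dense softmax head, trained with SGD+momentum.
It is small enough to train on a CPU in seconds on the synthetic tiles while
exercising exactly the same training contract (probability outputs, plateau
learning-rate schedule, learning curve) as a large pretrained backbone.

Layout convention: activations are float32 ``(N, C, H, W)``; convolutions are
3x3, stride 1, zero-padded to preserve spatial size; each block halves the
spatial resolution with a 2x2 max pool, so ``input_px`` must be divisible by
``2 ** n_blocks``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidArgumentError


class _Layer:
    def params(self):
        return []

    def grads(self):
        return []


class Conv3x3(_Layer):
    """3x3 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
        self._cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * 9
        )
        self._shape = (n, c, h, w)
        y = self._cols @ self.W.T + self.b
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, dy.shape[1])
        self.dW = (dyf.T @ self._cols).astype(np.float32)
        self.db = dyf.sum(axis=0).astype(np.float32)
        dcols = (dyf @ self.W).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(_Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise InvalidArgumentError("MaxPool2 needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dxr).reshape(n, c, h, w)


class GlobalAvgPool(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)).astype(
            np.float32
        )
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = (dy.T @ self._x).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return dy @ self.W


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Compact conv net: ``len(channels)`` conv blocks, GAP, softmax head."""

    def __init__(
        self,
        n_classes: int,
        input_px: int = 32,
        channels: tuple[int, ...] = (8, 16, 32),
        seed: int = 0,
    ):
        if n_classes < 2:
            raise InvalidArgumentError("need at least two classes")
        if input_px % (2 ** len(channels)):
            raise InvalidArgumentError(
                f"input_px={input_px} not divisible by 2^{len(channels)}"
            )
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.input_px = input_px
        self.channels = tuple(channels)
        self.layers: list[_Layer] = []
        c_in = 3
        for c_out in channels:
            self.layers += [Conv3x3(c_in, c_out, rng), ReLU(), MaxPool2()]
            c_in = c_out
        self.layers.append(GlobalAvgPool())
        self.head = Dense(c_in, n_classes, rng)
        self.layers.append(self.head)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Cross-entropy loss and accuracy on a batch; fills layer gradients."""
        logits = self.forward(x)
        probs = softmax(logits)
        n = len(y)
        eps = 1e-12
        loss = float(-np.log(probs[np.arange(n), y] + eps).mean())
        acc = float((probs.argmax(axis=1) == y).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grad = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, acc

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise InvalidArgumentError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise InvalidArgumentError("weight shape mismatch")
            p[...] = w


class SGDMomentum:
    """Classical momentum SGD: v <- mu*v - lr*g; w <- w + v."""

    def __init__(self, net: SmallCNN, momentum: float = 0.9):
        self.net = net
        self.momentum = momentum
        self.velocities = [np.zeros_like(p) for p in net.parameters()]

    def step(self, lr: float) -> None:
        for p, g, v in zip(self.net.parameters(), self.net.gradients(), self.velocities):
            v *= self.momentum
            v -= lr * g
            p += v
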