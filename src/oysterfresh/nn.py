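"""Minimal CNN engine: layers with hand-written backprop, plus Adam.

A compact, dependency-light stack sufficient for the 4-level oyster
graders: 2-D convolution (im2col + GEMM), ReLU, non-overlapping max
pooling, dense layers, softmax cross-entropy, and the Adam optimizer.
Every layer implements ``backward`` all the way to its *input*, so
gradients with respect to the image itself are available — the
activation-maximization visualizations depend on that.

Arrays are float32 in NCHW layout.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, Ho, Wo, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    n, c, ho, wo, _, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho, wo, c * k * k
    )


def _col2im(
    cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add inverse of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = cols.shape[1], cols.shape[2]
    cols = cols.reshape(n, ho, wo, c, k, k)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return out[:, :, pad : pad + h, pad : pad + w] if pad else out


class Conv2D(Layer):
    """2-D convolution (cross-correlation), He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, out_channels)).astype(
            np.float32
        )
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, padding
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.stride, self.pad)
        out = self._cols @ self.w + self.b  # (N, Ho, Wo, cout)
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.transpose(0, 2, 3, 1)  # (N, Ho, Wo, cout)
        n, ho, wo, _ = g.shape
        g2 = g.reshape(-1, self.out_channels)
        self.dw[...] = self._cols.reshape(-1, self._cols.shape[-1]).T @ g2
        self.db[...] = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(n, ho, wo, -1)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; spatial dims must divide the window."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        if h % s or w % s:
            raise ValueError(f"pool size {s} must divide spatial dims ({h}, {w})")
        xr = x.reshape(n, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # break ties: keep only the first max per window
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // s, w // s, -1)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(n, c, h // s, w // s, s, s).transpose(
            0, 1, 2, 4, 3, 5
        )
        self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        s = self.size
        g = grad[:, :, :, None, :, None] * self._mask
        return g.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Sequential:
    """Plain layer stack with end-to-end backprop to the input."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def forward_to(self, x: np.ndarray, index: int) -> np.ndarray:
        """Activations after ``layers[index]`` (inclusive)."""
        for layer in self.layers[: index + 1]:
            x = layer.forward(x)
        return x

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, (p, _) in enumerate(layer.params()):
                out[f"layer{i}_param{j}"] = p
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, value in self.state_arrays().items():
            value[...] = arrays[key]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
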