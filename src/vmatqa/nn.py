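"""Minimal NumPy neural-network layers with manual backprop.

The prediction network in this package is small (a few tens of thousands of
parameters), so its layers are implemented directly on NumPy arrays: 3x3
convolutions (as nine shifted tensor contractions), 3x3/3 max pooling, affine
maps, batch normalization, dropout and an Adam optimizer.  Everything is
deterministic given the seeds of the generators handed in, which is what
makes the training pipeline bit-reproducible.

Array convention: images are ``(N, C, H, W)``, feature vectors ``(N, F)``.
Gradient correctness is verified against finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return int(self.value.size)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1; ``pad=1`` keeps the spatial size."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        pad: int,
        rng: np.random.Generator,
        name: str = "conv",
        dtype=np.float32,
    ):
        self.pad = pad
        k = 3
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        self.W = Param(
            f"{name}.W",
            glorot_uniform(rng, (out_channels, in_channels, k, k), fan_in, fan_out, dtype),
        )
        self.b = Param(f"{name}.b", np.zeros(out_channels, dtype=dtype))
        self._cols: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, h, w = xp.shape
        ho, wo = h - 2, w - 2
        # im2col: one GEMM for all nine taps
        windows = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * 9)
        o = self.W.value.shape[0]
        out = cols @ self.W.value.reshape(o, c * 9).T + self.b.value
        self._cols = cols
        self._shape = (n, c, h, w)
        # non-contiguous view; the consumer's reshape makes its own copy
        return out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ho, wo = h - 2, w - 2
        o = grad.shape[1]
        dmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        self.W.grad += (dmat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value.reshape(o, c * 9)).reshape(n, ho, wo, c, 3, 3)
        dxp = np.zeros((n, c, h, w), dtype=grad.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        p = self.pad
        return dxp[:, :, p : h - p, p : w - p] if p else dxp


class MaxPool2D(Layer):
    """3x3 max pooling with stride 3, no padding (trailing remainder dropped)."""

    def __init__(self):
        self._idx: Optional[np.ndarray] = None
        self._in_shape: Optional[tuple] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = (h - 3) // 3 + 1, (w - 3) // 3 + 1
        r = x[:, :, : ho * 3, : wo * 3].reshape(n, c, ho, 3, wo, 3)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(n, c, ho, wo, 9)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        self._idx = idx
        self._in_shape = (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        ho, wo = grad.shape[2], grad.shape[3]
        d9 = np.zeros((n, c, ho, wo, 9), dtype=grad.dtype)
        np.put_along_axis(d9, self._idx[..., None], grad[..., None], axis=-1)
        d9 = d9.reshape(n, c, ho, wo, 3, 3).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, : ho * 3, : wo * 3] = d9.reshape(n, c, ho * 3, wo * 3)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Affine(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator,
        name: str = "affine",
        dtype=np.float32,
    ):
        self.W = Param(
            f"{name}.W",
            glorot_uniform(rng, (in_features, out_features), in_features, out_features, dtype),
        )
        self.b = Param(f"{name}.b", np.zeros(out_features, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class BatchNorm1D(Layer):
    """Batch normalization over a feature vector (2 learnable params/feature)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn", dtype=np.float32):
        self.gamma = Param(f"{name}.gamma", np.ones(n_features, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(n_features, dtype=dtype))
        self.running_mean = np.zeros(n_features, dtype=dtype)
        self.running_var = np.ones(n_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            # normalize with the biased batch variance, but track the
            # unbiased one so inference statistics estimate the population
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(self.running_mean.dtype)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * unbiased
            ).astype(self.running_var.dtype)
        else:
            mu = self.running_mean
            var = self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xc = x - mu
        self._xhat = self._xc * self._ivar
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        dxhat = grad * self.gamma.value
        # standard batch-norm backward (training-mode statistics)
        return (
            ivar / n * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        ).astype(grad.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Iterable[Param], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            p.value -= (self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)).astype(
                p.value.dtype
            )
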