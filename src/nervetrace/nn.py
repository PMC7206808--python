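"""Minimal CPU neural-network engine for encoder-decoder segmentation.

Implements exactly the building blocks the segmentation architectures need
(3x3/1x1 convolution, batch normalization, ReLU, 2x2 max pooling, 2x nearest
upsampling, channel concatenation, dropout, softmax cross-entropy) with
hand-written backward passes and the Adam optimizer, in float32 NumPy.

Arrays are laid out NHWC. Convolutions use im2col built from k*k shifted
slices of the zero-padded input, so the heavy lifting is a single BLAS
matmul per layer; the backward pass scatters gradients back with the same
k*k slice structure. Everything is deterministic for a fixed seed on CPU,
which makes seeded training bit-reproducible.

Gradient correctness is verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "Dropout",
    "ConvBNReLU",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A learnable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D:
    """Same-padding stride-1 convolution, NHWC, weight shape (k*k*cin, cout).

    Evaluated as k*k shifted matmuls against the zero-padded input rather
    than one big im2col matrix: the shifted slices copy contiguously, which
    is substantially faster on CPU for the channel widths used here, and the
    backward pass only needs the padded input, not a k*k-times-larger column
    matrix.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        bias: bool = True,
        name: str = "conv",
    ) -> None:
        self.cin, self.cout, self.k = cin, cout, kernel
        fan_in = kernel * kernel * cin
        self.weight = Param(_he_init(rng, (fan_in, cout), fan_in), f"{name}.weight")
        self.bias = Param(np.zeros(cout), f"{name}.bias") if bias else None
        self._xp: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        if not p:
            return x
        n, h, w, c = x.shape
        xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        xp[:, p : p + h, p : p + w, :] = x
        return xp

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        xp = self._pad(x)
        self._xshape = x.shape
        self._xp = xp if train else None
        out = np.zeros((n * h * w, self.cout), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                w_ij = self.weight.value[(i * k + j) * c : (i * k + j + 1) * c]
                xs = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :])
                out += xs.reshape(-1, c) @ w_ij
        if self.bias is not None:
            out += self.bias.value
        return out.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k = self.k
        p = k // 2
        xp = self._xp
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.cout)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = (i * k + j) * c
                w_ij = self.weight.value[sl : sl + c]
                xs = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :])
                self.weight.grad[sl : sl + c] += xs.reshape(-1, c).T @ dy2
                dxp[:, i : i + h, j : j + w, :] += (dy2 @ w_ij.T).reshape(n, h, w, c)
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class BatchNorm2D:
    """Per-channel batch normalization with learnable scale and shift."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std.astype(np.float32), x.shape)
        return (xhat * self.gamma.value + self.beta.value).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += np.sum(dy * xhat, axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
        ) * inv_std
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    def __init__(self) -> None:
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # route gradient to every tied maximum (deterministic)
            mask = xr == out[:, :, None, :, None, :]
            self._cache = (mask, x.shape)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        n, h, w, c = shape
        dx = mask * dy[:, :, None, :, None, :]
        self._cache = None
        return dx.reshape(n, h, w, c).astype(np.float32)


class UpsampleNearest2x:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return (
            dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)
        )


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(
        self, x: np.ndarray, train: bool = True, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class ConvBNReLU:
    """The conv(no bias) -> batch-norm -> ReLU unit used throughout."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, name: str) -> None:
        self.conv = Conv2D(cin, cout, kernel, rng, bias=False, name=name)
        self.bn = BatchNorm2D(cout, name=name)
        self.relu = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last (channel) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted per-pixel categorical cross-entropy.

    ``logits`` is (N, H, W, C), ``labels`` (N, H, W) integer class indices.
    Returns the scalar loss (normalized by the total weight so that the
    unweighted case is the plain per-pixel mean) and d(loss)/d(logits).
    """
    p = softmax(logits.astype(np.float64))
    n, h, w, c = logits.shape
    onehot = np.eye(c, dtype=np.float64)[labels]
    if class_weights is None:
        weights = np.ones((n, h, w))
    else:
        weights = np.asarray(class_weights, dtype=np.float64)[labels]
    total = weights.sum()
    logp = np.log(np.clip(p, 1e-12, None))
    loss = -np.sum(weights * np.sum(onehot * logp, axis=-1)) / total
    dlogits = (p - onehot) * weights[..., None] / total
    return float(loss), dlogits.astype(np.float32)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
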