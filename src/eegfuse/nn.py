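"""Minimal 1-D convolutional network layers with analytic gradients.

All layers operate on ``(batch, time, channels)`` float arrays and expose

- ``forward(x, training)``   -> output, caching what backward needs,
- ``backward(grad_out)``     -> grad wrt input, filling ``self.grads``,
- ``params`` / ``grads``     -> dicts of learnable arrays and their grads.

Convolutions are evaluated as a single matrix product against an im2col
view, which is where essentially all the compute lives. Gradients of every
layer are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "AvgPool1D",
    "GlobalAvgPool1D",
    "BatchNorm1D",
    "SpatialDropout1D",
    "Dropout",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
    "conv_out_len",
]


def conv_out_len(n: int, kernel: int, stride: int, padding: str) -> int:
    """Output length of a 1-D convolution stage."""
    if padding == "same":
        return -(-n // stride)  # ceil(n / stride)
    if padding == "valid":
        if n < kernel:
            raise ValueError(
                f"input length {n} is below the kernel size {kernel} "
                f"(minimum valid length {kernel})"
            )
        return (n - kernel) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


class Layer:
    """Base class: stateless by default, no parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution with 'same' or 'valid' padding and ReLU-free output.

    Weight shape is ``(kernel * c_in, c_out)``; initialization is uniform
    Glorot (fan-in + fan-out) from the supplied generator.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 5,
        stride: int = 1,
        padding: str = "valid",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng if rng is not None else np.random.default_rng()
        fan_in, fan_out = kernel * c_in, kernel * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["W"] = rng.uniform(-limit, limit, (kernel * c_in, c_out)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def _pad(self, n: int) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        out = conv_out_len(n, self.kernel, self.stride, "same")
        total = max((out - 1) * self.stride + self.kernel - n, 0)
        return total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, n, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        left, right = self._pad(n)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0))) if left or right else x
        out_len = conv_out_len(n, self.kernel, self.stride, self.padding)
        # (b, positions, c, kernel) view -> (b, out_len, kernel*c) matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, :: self.stride][:, :out_len]
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            b, out_len, self.kernel * c
        )
        self._cache = (cols, n, left, right, xp.shape[1])
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, n, left, right, n_pad = self._cache
        b, out_len, _ = grad.shape
        gmat = grad.reshape(b * out_len, self.c_out)
        self.grads["W"] = cols.reshape(b * out_len, -1).T @ gmat
        self.grads["b"] = gmat.sum(axis=0)
        dcols = (gmat @ self.params["W"].T).reshape(
            b, out_len, self.kernel, self.c_in
        )
        dxp = np.zeros((b, n_pad, self.c_in), dtype=grad.dtype)
        pos = self.stride * np.arange(out_len)
        for j in range(self.kernel):
            # positions are unique for stride >= 1, so fancy += is safe
            dxp[:, pos + j, :] += dcols[:, :, j, :]
        return dxp[:, left : n_pad - right if right else n_pad]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AvgPool1D(Layer):
    """Non-overlapping average pooling; a trailing partial window is dropped."""

    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, n, c = x.shape
        out_len = n // self.pool
        self._in_len = n
        return x[:, : out_len * self.pool].reshape(b, out_len, self.pool, c).mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, out_len, c = grad.shape
        dx = np.zeros((b, self._in_len, c), dtype=grad.dtype)
        dx[:, : out_len * self.pool] = np.repeat(grad / self.pool, self.pool, axis=1)
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._in_len, axis=1) / self._in_len


class BatchNorm1D(Layer):
    """Batch normalization over (batch, time) per feature map."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3, dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=dtype)
        self.params["beta"] = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, training, x.ndim)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, training, ndim = self._cache
        axes = tuple(range(ndim - 1))
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"] * inv
        if not training:
            return grad * g
        n = np.prod([grad.shape[a] for a in axes])
        return (g / n) * (
            n * grad
            - grad.sum(axis=axes, keepdims=True)
            - xhat * (grad * xhat).sum(axis=axes, keepdims=True)
        )


class SpatialDropout1D(Layer):
    """Drops whole feature maps (channels) per sample during training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random((x.shape[0], 1, x.shape[2])) < keep
        self._mask = mask.astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dropout(Layer):
    """Element-wise inverted dropout."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        limit = np.sqrt(6.0 / (c_in + c_out))
        self.params["W"] = rng.uniform(-limit, limit, (c_in, c_out)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def named_params(self, prefix: str = "") -> dict[str, tuple[Layer, str]]:
        out: dict[str, tuple[Layer, str]] = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_params(f"{prefix}{i}."))
            else:
                for name in layer.params:
                    out[f"{prefix}{i}.{name}"] = (layer, name)
        return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient wrt the logits.

    ``probs`` are softmax outputs; ``y`` integer class labels. The returned
    gradient is ``(probs - onehot) / batch`` (softmax and loss fused).
    """
    b = probs.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(b), y] + eps).mean()
    grad = probs.copy()
    grad[np.arange(b), y] -= 1.0
    return float(loss), grad / b


class Adam:
    """Adam with an inverse-time learning-rate schedule.

    The step-``t`` learning rate is ``lr / (1 + decay * t)``; with
    ``decay = 0`` the rate is constant.
    """

    def __init__(
        self,
        named_params: dict[str, tuple[Layer, str]],
        lr: float = 1e-3,
        decay: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.named_params = named_params
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {k: np.zeros_like(layer.params[n]) for k, (layer, n) in named_params.items()}
        self._v = {k: np.zeros_like(layer.params[n]) for k, (layer, n) in named_params.items()}

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.decay * self.t)
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for key, (layer, name) in self.named_params.items():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self._m[key]
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = lr_t * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
            layer.params[name] -= update.astype(layer.params[name].dtype)
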