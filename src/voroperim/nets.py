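"""Minimal feed-forward network stack in numpy.

The classifier networks used here are deliberately small (five convolutional
layers of four 3x3 filters, two 32-unit dense layers), so the package carries
its own compact layer implementations with exact reverse-mode gradients
rather than depending on a deep-learning framework.  Gradients are exact
reverse-mode derivatives (verified against central finite differences in the
test suite), and the backward pass also yields the gradient of the output
with respect to the *input image*, which is what the saliency maps
differentiate.  Training runs in float32 by default (the nets are
memory-bandwidth bound); ``Sequential.astype`` switches to float64 wherever
extra precision matters, e.g. finite-difference checks and inference-time
input gradients.

Conventions: convolutional tensors are channels-last, (batch, height, width,
channels); dense tensors are (batch, features).  ``forward(x, train=...)``
caches what ``backward(grad)`` needs; layers are therefore not reentrant,
which is fine for the sequential use in this package.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def __init__(self):
        self.params: dict[str, Parameter] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = Parameter(_glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.params["b"] = Parameter(np.zeros(n_out))

    def forward(self, x, train, rng=None):
        self._x = x
        return x @ self.params["W"].value + self.params["b"].value

    def backward(self, g):
        self.params["W"].grad += self._x.T @ g
        self.params["b"].grad += g.sum(axis=0)
        return g @ self.params["W"].value.T


class Conv2d(Layer):
    """3x3 (or kxk) convolution, 'same' zero padding, stride 1, channels-last.

    Implemented as k*k shifted GEMMs on the padded input: for each kernel
    offset, a contiguous copy of the shifted window is multiplied by that
    offset's (in, out) weight block.  This avoids the scattered im2col
    gather and keeps every matrix product in BLAS.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported (same padding)")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        # weights stored as (k, k, in_ch, out_ch): one GEMM block per offset
        self.params["W"] = Parameter(
            _glorot_uniform(rng, (kernel, kernel, in_ch, out_ch), fan_in, fan_out)
        )
        self.params["b"] = Parameter(np.zeros(out_ch))

    def forward(self, x, train, rng=None):
        B, H, W, C = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        Wk = self.params["W"].value
        out = np.tile(self.params["b"].value, (B, H, W, 1))
        shifts = []
        for di in range(k):
            for dj in range(k):
                v = np.ascontiguousarray(xp[:, di : di + H, dj : dj + W, :])
                shifts.append(v)
                out += v @ Wk[di, dj]
        self._shifts, self._in_shape = shifts, x.shape
        return out

    def backward(self, g):
        B, H, W, C = self._in_shape
        k, p = self.k, self.k // 2
        Wk = self.params["W"].value
        g2 = g.reshape(-1, self.out_ch)
        self.params["b"].grad += g2.sum(axis=0)
        gxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=g.dtype)
        for di in range(k):
            for dj in range(k):
                v = self._shifts[di * k + dj]
                self.params["W"].grad[di, dj] += v.reshape(-1, C).T @ g2
                gxp[:, di : di + H, dj : dj + W, :] += g @ Wk[di, dj].T
        return gxp[:, p : p + H, p : p + W, :]


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial dims for conv input).

    Training mode normalizes with batch statistics and updates exponential
    running averages; inference mode uses the running statistics, making the
    layer a fixed affine map (important for saliency gradients).
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = Parameter(np.ones(n_features))
        self.params["beta"] = Parameter(np.zeros(n_features))
        self.buffers["running_mean"] = np.zeros(n_features)
        self.buffers["running_var"] = np.ones(n_features)

    def _axes_shape(self, x):
        # features live on the last axis (channels-last for conv maps)
        if x.ndim not in (2, 4):
            raise ValueError("BatchNorm expects 2-D or 4-D input")
        return tuple(range(x.ndim - 1)), (1,) * (x.ndim - 1) + (-1,)

    def forward(self, x, train, rng=None):
        axes, bshape = self._axes_shape(x)
        gamma = self.params["gamma"].value.reshape(bshape)
        beta = self.params["beta"].value.reshape(bshape)
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mu.ravel()
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var.ravel()
        else:
            mu = self.buffers["running_mean"].reshape(bshape)
            var = self.buffers["running_var"].reshape(bshape)
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, axes, bshape, train, x.shape)
        return gamma * xhat + beta

    def backward(self, g):
        xhat, ivar, axes, bshape, train, shape = self._cache
        gamma = self.params["gamma"].value.reshape(bshape)
        sum_g = g.sum(axis=axes, keepdims=True)
        sum_gx = (g * xhat).sum(axis=axes, keepdims=True)
        self.params["gamma"].grad += sum_gx.ravel()
        self.params["beta"].grad += sum_g.ravel()
        if not train:
            return g * (gamma * ivar)
        # standard batch-norm backward, folded so the parameter-gradient
        # reductions are reused (dxhat sums are gamma times these sums)
        N = np.prod([shape[a] for a in axes])
        return (gamma * ivar / N) * (N * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x, train, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, ceil mode (odd sizes padded with -inf)."""

    def forward(self, x, train, rng=None):
        B, H, W, C = x.shape
        Ho, Wo = -(-H // 2), -(-W // 2)
        xp = np.full((B, Ho * 2, Wo * 2, C), -np.inf, dtype=x.dtype)
        xp[:, :H, :W, :] = x
        blocks = xp.reshape(B, Ho, 2, Wo, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(
            B, Ho, Wo, 4, C
        )
        self._argmax = blocks.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._argmax[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g):
        B, H, W, C = self._in_shape
        Ho, Wo = -(-H // 2), -(-W // 2)
        gb = np.zeros((B, Ho, Wo, 4, C), dtype=g.dtype)
        np.put_along_axis(gb, self._argmax[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gxp = gb.reshape(B, Ho, Wo, 2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(
            B, Ho * 2, Wo * 2, C
        )
        return gxp[:, :H, :W, :]


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C) by spatial averaging of each feature map."""

    def forward(self, x, train, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        B, H, W, C = self._in_shape
        return np.broadcast_to(g[:, None, None, :], (B, H, W, C)) / (H * W)


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout needs an rng in training mode")
        self._mask = ((rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._in_shape)


class Sequential:
    """A plain layer stack with reverse-mode backward to the input."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng=None) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, g) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params.values()]

    def astype(self, dtype) -> "Sequential":
        """Cast all parameters and buffers to ``dtype`` (in place).

        Training runs in float32 by default (the nets are tiny and
        memory-bandwidth bound); float64 is used where gradient checks
        against finite differences need the extra precision.
        """
        for layer in self.layers:
            for p in layer.params.values():
                p.value = p.value.astype(dtype)
                p.grad = p.grad.astype(dtype)
            for name in list(layer.buffers):
                layer.buffers[name] = layer.buffers[name].astype(dtype)
        return self

    @property
    def dtype(self):
        for layer in self.layers:
            for p in layer.params.values():
                return p.value.dtype
        return np.dtype(float)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p.value.copy()
            for name, buf in layer.buffers.items():
                state[f"{i}.buf.{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                p.value = np.asarray(state[f"{i}.{name}"], dtype=float).copy()
                p.grad = np.zeros_like(p.value)
            for name in list(layer.buffers):
                layer.buffers[name] = np.asarray(state[f"{i}.buf.{name}"], dtype=float).copy()


class Adam:
    """Adam optimizer with bias correction (defaults lr 1e-3, 0.9/0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.ravel()
    y = np.asarray(y, dtype=float).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).reshape(logits.shape).astype(logits.dtype)
    return loss, grad
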