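"""Minimal CPU neural-network engine used by the denoisers and CNN observers.

Implements exactly the pieces the networks in this package need: 3x3
same-padded convolutions, batch normalization, ReLU, global average
pooling, dense heads, image/feature MSE and binary cross-entropy losses,
and the Adam optimizer.  Activations are float32 arrays in channels-last
layout ``(N, H, W, C)``; convolutions run as im2col + BLAS matmul, which
is the throughput-optimal formulation on a single CPU core at these
problem sizes.

Backward passes are hand-derived.  Convolution input gradients are
computed as a convolution of the output gradient with the spatially
flipped, channel-transposed kernel, so no scatter-add (col2im) is ever
required.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """im2col for a 3x3 same-padded convolution.

    x: (N, H, W, C) -> (N*H*W, 9*C) with column order (ky, kx, c), c fastest.
    """
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)
    return np.ascontiguousarray(cols)


class Conv2d:
    """3x3 convolution, zero-padded 'same', with bias.

    Weights are stored as (3, 3, c_in, c_out).  Glorot-uniform
    initialization (the engine default for every layer type).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in, fan_out = 9 * c_in, 9 * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(3, 3, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        # training-loop knobs: keep the im2col matrix from the forward pass
        # (trades RAM for a backward-pass recompute) and skip the input
        # gradient on the network's first layer where nothing consumes it
        self.cache_cols = False
        self.needs_input_grad = True
        self._x: np.ndarray | None = None
        self._cols: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col3(x)
        if training:
            self._x = x
            self._cols = cols if self.cache_cols else None
        out = cols @ self.weight.value.reshape(9 * self.c_in, self.c_out)
        out += self.bias.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        n, h, w, _ = dout.shape
        d2 = dout.reshape(n * h * w, self.c_out)
        cols = self._cols if self._cols is not None else _im2col3(self._x)
        self.weight.grad += (cols.T @ d2).reshape(3, 3, self.c_in, self.c_out)
        self.bias.grad += d2.sum(axis=0)
        self._x = self._cols = None
        del cols
        if not self.needs_input_grad:
            return None
        # dx = conv(dout, rot180(W) with channels transposed)
        w_rot = np.flip(self.weight.value, (0, 1)).transpose(0, 1, 3, 2)
        dcols = _im2col3(dout)
        dx = dcols @ w_rot.reshape(9 * self.c_out, self.c_in)
        return dx.reshape(n, h, w, self.c_in)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W).

    Running statistics (momentum 0.9, eps 1e-5) are used at inference so
    that ``denoise`` is deterministic.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * ivar
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(np.float32)
            self._cache = (xhat, ivar)
            return self.gamma.value * xhat + self.beta.value
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * (x - self.running_mean) * ivar + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dg = (dout * xhat).sum(axis=(0, 1, 2))
        db = dout.sum(axis=(0, 1, 2))
        self.gamma.grad += dg
        self.beta.grad += db
        dx = (self.gamma.value * ivar / m) * (m * dout - db - xhat * dg)
        self._cache = None
        return dx.astype(np.float32)


class GlobalAvgPool:
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self):
        self._shape = None

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(np.float32)


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (c_in + c_out))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self._x = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list):
        self.layers = list(layers)

    def params(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:
                break
        return dout


class Adam:
    """Classic Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def tune_conv_layers(layers, batch_size: int, pixels: int,
                     budget_bytes: float = 1.5e9) -> None:
    """Set per-conv training knobs for a layer list in forward order.

    The first convolution never needs an input gradient; im2col caching
    is enabled greedily until ``budget_bytes`` of extra RAM is committed.
    """
    convs = [l for l in layers if isinstance(l, Conv2d)]
    if convs:
        convs[0].needs_input_grad = False
    total = 0.0
    for conv in convs:
        size = batch_size * pixels * 9 * conv.c_in * 4
        conv.cache_cols = total + size <= budget_bytes
        if conv.cache_cols:
            total += size


def mse_image_loss(out: np.ndarray, target: np.ndarray):
    """Mean over the batch of the squared L2 norm per image.

    Returns (loss, grad wrt out).  Note this is a per-image *sum* over
    pixels, averaged over the batch; Adam is invariant to the overall
    loss scale, so the convention only affects reported loss values.
    """
    n = out.shape[0]
    diff = out - target
    loss = float((diff.astype(np.float64) ** 2).sum() / n)
    return loss, (2.0 / n) * diff


def bce_with_logits(z: np.ndarray, y: np.ndarray):
    """Binary cross-entropy on logits z (N,) with labels y in {0,1}."""
    z = z.astype(np.float64)
    n = z.shape[0]
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / n).astype(np.float32)
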