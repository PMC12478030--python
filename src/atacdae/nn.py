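"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the hierarchical 1D convolutional autoencoder needs: strided 1D
convolutions and their transposed counterparts, dense layers, batch
normalization, dropout, the usual activations, and an Adam optimizer.
All parameters are float32; gradients are accumulated per backward pass
and consumed by :class:`Adam`.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) for dense layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "ConvTranspose1d",
    "Dense",
    "BatchNorm1d",
    "Dropout",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Sequential",
    "Adam",
    "softmax",
]

_DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DTYPE)


class Conv1d(Layer):
    """1D convolution, kernel ``k``, stride ``s``, symmetric zero padding ``p``.

    Output length is ``(L + 2p - k) // s + 1``.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.W = Param(_he_init(rng, (c_out, c_in, kernel), c_in * kernel), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=_DTYPE), f"{name}.b")
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.pad:
            xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        else:
            xp = x
        # (B, C, L_out, k) strided view of every receptive field
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        out = np.tensordot(win, self.W.value, axes=[(1, 3), (1, 2)])  # (B, L_out, C_out)
        out += self.b.value
        out = np.ascontiguousarray(out.transpose(0, 2, 1))
        self._cache = (x.shape, win)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, win = self._cache
        B, _, L = x_shape
        L_out = dout.shape[2]
        self.b.grad += dout.sum(axis=(0, 2))
        # dW: contract batch and output-position axes
        self.W.grad += np.tensordot(dout, win, axes=[(0, 2), (0, 2)])
        # gradient w.r.t. the window view, then scatter-add back
        dwin = np.tensordot(dout, self.W.value, axes=[(1,), (0,)])  # (B, L_out, C_in, k)
        dwin = dwin.transpose(0, 2, 1, 3)  # (B, C_in, L_out, k)
        dxp = np.zeros((B, self.c_in, L + 2 * self.pad), dtype=dout.dtype)
        for t in range(self.kernel):
            dxp[:, :, t:t + self.stride * L_out:self.stride] += dwin[:, :, :, t]
        if self.pad:
            return dxp[:, :, self.pad:-self.pad]
        return dxp


class ConvTranspose1d(Layer):
    """Transposed 1D convolution (the adjoint of :class:`Conv1d`).

    Output length is ``(L - 1) * s + k - 2p``; with ``k=4, s=2, p=1`` it
    exactly doubles the input length, mirroring the stride-2 encoder.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 name: str = "convT") -> None:
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.W = Param(_he_init(rng, (c_in, c_out, kernel), c_in * kernel), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=_DTYPE), f"{name}.b")
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, _, L = x.shape
        full_len = (L - 1) * self.stride + self.kernel
        full = np.zeros((B, self.c_out, full_len), dtype=x.dtype)
        for t in range(self.kernel):
            contrib = np.tensordot(x, self.W.value[:, :, t], axes=[(1,), (0,)])  # (B, L, C_out)
            full[:, :, t:t + self.stride * (L - 1) + 1:self.stride] += contrib.transpose(0, 2, 1)
        out = full[:, :, self.pad:full_len - self.pad] if self.pad else full
        out = out + self.b.value[None, :, None]
        self._cache = x
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        B, _, L = x.shape
        full_len = (L - 1) * self.stride + self.kernel
        dfull = np.zeros((B, self.c_out, full_len), dtype=dout.dtype)
        if self.pad:
            dfull[:, :, self.pad:full_len - self.pad] = dout
        else:
            dfull[:] = dout
        self.b.grad += dout.sum(axis=(0, 2))
        dx = np.zeros_like(x)
        for t in range(self.kernel):
            sl = dfull[:, :, t:t + self.stride * (L - 1) + 1:self.stride]  # (B, C_out, L)
            self.W.grad[:, :, t] += np.tensordot(x, sl, axes=[(0, 2), (0, 2)])
            dx += np.tensordot(sl, self.W.value[:, :, t], axes=[(1,), (1,)]).transpose(0, 2, 1)
        return dx


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None,
                 name: str = "dense") -> None:
        rng = rng or np.random.default_rng()
        self.W = Param(_he_init(rng, (f_in, f_out), f_in), f"{name}.W")
        self.b = Param(np.zeros(f_out, dtype=_DTYPE), f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis of (batch, features) input."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(n_features, dtype=_DTYPE), f"{name}.gamma")
        self.beta = Param(np.zeros(n_features, dtype=_DTYPE), f"{name}.beta")
        self.running_mean = np.zeros(n_features, dtype=_DTYPE)
        self.running_var = np.ones(n_features, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(_DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, train)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not train:
            return dxhat * inv_std
        B = dout.shape[0]
        return (inv_std / B) * (B * dxhat - dxhat.sum(axis=0)
                                - xhat * (dxhat * xhat).sum(axis=0))


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Draws from an injected RNG."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(dout.dtype, copy=False)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a (batch, classes) logit matrix."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
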