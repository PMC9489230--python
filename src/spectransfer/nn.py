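"""Minimal numpy neural-net engine for 1D spectral regression.

Forward/backward passes for the layer set the spectral CNNs need —
``Conv1d`` (stride 1), ``MaxPool1d``, ``BatchNorm1d``, ``ReLU``,
``Flatten``, ``Dense`` — plus an Adam optimizer.  Everything is plain
numpy in float32, bit-reproducible given a seed, and supports:

* per-layer freezing (frozen BatchNorm runs in inference mode and its
  running statistics stop updating), and
* gradients of the scalar output with respect to the *input* spectrum,
  the primitive behind gradient saliency maps.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) after ``Flatten``.
"""
from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

__all__ = ["Layer", "Conv1d", "MaxPool1d", "BatchNorm1d", "ReLU", "Flatten",
           "Dense", "Network", "Adam", "mse_loss"]

_F = np.float32


class Layer:
    """Base layer: stateless unless it overrides ``params``."""

    frozen = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """1D convolution, stride 1, no padding ('valid')."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                 size=(out_channels, fan_in)).astype(_F)
        self.bias = np.zeros(out_channels, dtype=_F)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def out_length(self, in_len: int) -> int:
        return in_len - self.kernel_size + 1

    def forward(self, x, train):
        n, c, length = x.shape
        self._in_len = length
        k = self.kernel_size
        windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
        # (n, c, L_out, k) -> (n, L_out, c*k)
        cols = windows.transpose(0, 2, 1, 3).reshape(n, length - k + 1, c * k)
        self._cols = cols  # kept in eval mode too: input gradients need it
        out = cols @ self.weight.T + self.bias  # (n, L_out, out_ch)
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad):
        n, _, l_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (n, L_out, out_ch)
        cols = self._cols
        self.d_weight[...] = np.tensordot(g, cols, axes=([0, 1], [0, 1]))
        self.d_bias[...] = g.sum(axis=(0, 1))
        d_cols = g @ self.weight  # (n, L_out, c*k)
        d_cols = d_cols.reshape(n, l_out, self.in_channels, self.kernel_size)
        dx = np.zeros((n, self.in_channels, self._in_len), dtype=_F)
        for j in range(self.kernel_size):
            dx[:, :, j:j + l_out] += d_cols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.d_weight, self.d_bias]


class MaxPool1d(Layer):
    """Max pooling, window = stride = ``size`` (default 2), floor semantics."""

    def __init__(self, size: int = 2):
        self.size = size
        self._argmax: np.ndarray | None = None
        self._in_len = 0

    def out_length(self, in_len: int) -> int:
        return in_len // self.size

    def forward(self, x, train):
        n, c, length = x.shape
        self._in_len = length
        l_out = length // self.size
        if l_out < 1:
            raise ValueError(f"pooling reduces length {length} below 1")
        xr = x[:, :, :l_out * self.size].reshape(n, c, l_out, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        dxr = np.zeros((n, c, l_out, self.size), dtype=_F)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=_F)
        dx[:, :, :l_out * self.size] = dxr.reshape(n, c, l_out * self.size)
        return dx


class BatchNorm1d(Layer):
    """Batch normalization over the batch (and length, for conv inputs).

    Normalizes per channel for (n, c, l) inputs and per feature for (n, f)
    inputs; affine scale/shift; exponential running statistics for
    inference.  A frozen BatchNorm always uses its running statistics.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = np.ones(num_features, dtype=_F)
        self.beta = np.zeros(num_features, dtype=_F)
        self.d_gamma = np.zeros_like(self.gamma)
        self.d_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(num_features, dtype=_F)
        self.running_var = np.ones(num_features, dtype=_F)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def _moments_axes(self, x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _bcast(self, v, ndim):
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, train):
        axes = self._moments_axes(x)
        use_batch = train and not self.frozen
        if use_batch:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.shape[0] * (x.shape[2] if x.ndim == 3 else 1)
            self.running_mean += self.momentum * (mean - self.running_mean)
            # unbiased running variance, biased batch variance for normalization
            unbiased = var * m / max(m - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._bcast(mean, x.ndim)) * self._bcast(inv_sd, x.ndim)
        self._cache = (xhat, inv_sd, use_batch)
        return self._bcast(self.gamma, x.ndim) * xhat + self._bcast(self.beta, x.ndim)

    def backward(self, grad):
        xhat, inv_sd, used_batch = self._cache
        axes = self._moments_axes(grad)
        self.d_gamma[...] = (grad * xhat).sum(axis=axes)
        self.d_beta[...] = grad.sum(axis=axes)
        gi = self._bcast(self.gamma * inv_sd, grad.ndim)
        if not used_batch:
            return (grad * gi).astype(_F)
        m = grad.shape[0] * (grad.shape[2] if grad.ndim == 3 else 1)
        mean_dy = self._bcast(grad.sum(axis=axes) / m, grad.ndim)
        mean_dy_xhat = self._bcast((grad * xhat).sum(axis=axes) / m, grad.ndim)
        return (gi * (grad - mean_dy - xhat * mean_dy_xhat)).astype(_F)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.d_gamma, self.d_beta]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = rng.normal(0.0, np.sqrt(2.0 / in_features),
                                 size=(in_features, out_features)).astype(_F)
        self.bias = np.zeros(out_features, dtype=_F)
        self.d_weight = np.zeros_like(self.weight)
        self.d_bias = np.zeros_like(self.bias)

    def forward(self, x, train):
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad):
        self.d_weight[...] = self._x.T @ grad
        self.d_bias[...] = grad.sum(axis=0)
        return grad @ self.weight.T

    def params(self):
        return [self.weight, self.bias]

    def grads(self):
        return [self.d_weight, self.d_bias]


class Network:
    """An ordered layer stack mapping (n, 1, width) spectra to (n,) outputs."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.asarray(x, dtype=_F)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.asarray(grad, dtype=_F)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions, batched to bound memory."""
        x = np.asarray(x, dtype=_F)
        outs = [self.forward(x[i:i + batch_size], train=False).ravel()
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs) if outs else np.empty(0)

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(output)/d(input) per sample, in inference mode."""
        x = np.asarray(x, dtype=_F)
        out = self.forward(x, train=False)
        return self.backward(np.ones_like(out))

    # -- parameter plumbing ------------------------------------------------
    def trainable_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params() and not l.frozen]

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.trainable_layers() for p in l.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.trainable_layers() for g in l.grads()]

    def state(self) -> list[np.ndarray]:
        """Copies of every parameter and BN running statistic."""
        out = []
        for l in self.layers:
            out.extend(p.copy() for p in l.params())
            if isinstance(l, BatchNorm1d):
                out.extend([l.running_mean.copy(), l.running_var.copy()])
        return out

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        it = iter(state)
        for l in self.layers:
            for p in l.params():
                p[...] = next(it)
            if isinstance(l, BatchNorm1d):
                l.running_mean[...] = next(it)
                l.running_var[...] = next(it)

    def clone(self) -> "Network":
        return copy.deepcopy(self)

    def n_parameters(self) -> int:
        return sum(p.size for l in self.layers for p in l.params())


class Adam:
    """Adaptive moment estimation with an externally scheduled learning rate."""

    def __init__(self, params: Sequence[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: Sequence[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """L2 loss (mean squared error) and its gradient w.r.t. predictions."""
    diff = pred.ravel() - target.ravel()
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff.astype(_F)
    return loss, grad.reshape(pred.shape)
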