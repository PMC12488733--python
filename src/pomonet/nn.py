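"""Neural-network layers and the Adam optimizer, on the autograd engine.

Only the building blocks the three spectral architectures use: dense and 1-D
convolutional layers, batch normalization, ReLU, dropout, windowed max
pooling, gated recurrent units (run forward or reversed for the
bidirectional pair), and single-head dot-product self-attention.
"""

from __future__ import annotations

import math

import numpy as np

from pomonet.autograd import Tensor, concat, conv1d, max_pool1d, softmax

__all__ = [
    "Module", "Dense", "Conv1d", "BatchNorm1d", "ReLU", "Dropout",
    "MaxPool1d", "Flatten", "GRU", "SelfAttention", "Sequential", "Adam",
]


class Parameter(Tensor):
    """A trainable tensor; ``decay`` marks it for L2 regularization."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = True):
        super().__init__(data, requires_grad=True)
        self.decay = decay


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.bias = Parameter(np.zeros(n_out), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """'Same' 1-D convolution: kernel 3, pad 1 keeps the band axis length."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.weight = Parameter(
            _glorot(rng, (c_out, c_in, kernel), fan_in, fan_out))
        self.bias = Parameter(np.zeros(c_out), decay=False)
        self.pad = (kernel - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.pad)


class BatchNorm1d(Module):
    """Per-channel normalization over batch and length axes of (B, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.squeeze())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.squeeze())
            normed = centered * (var + self.eps) ** -0.5
        else:
            mean = self.running_mean.reshape(1, -1, 1)
            std = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            normed = (x - Tensor(mean)) * Tensor(1.0 / std)
        shape = (1, -1, 1)
        return normed * self.gamma.reshape(*shape) + self.beta.reshape(*shape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.data.shape) / keep
        return x * Tensor(mask)


class MaxPool1d(Module):
    def __init__(self, size: int):
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return max_pool1d(x, self.size)


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.data.shape[0], -1)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class GRU(Module):
    """Single-layer gated recurrent unit; returns the final hidden state.

    ``reverse=True`` consumes the band sequence long-to-short, providing the
    backward half of a bidirectional pair.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False):
        self.hidden = hidden
        self.reverse = reverse
        # gate order: update (z), reset (r), candidate (n)
        self.w_x = Parameter(_glorot(rng, (n_in, 3 * hidden), n_in, hidden))
        self.w_h = Parameter(_glorot(rng, (hidden, 3 * hidden), hidden, hidden))
        self.bias = Parameter(np.zeros(3 * hidden), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        batch, length, _ = x.data.shape
        h = Tensor(np.zeros((batch, self.hidden)))
        hid = self.hidden
        steps = range(length - 1, -1, -1) if self.reverse else range(length)
        for t in steps:
            x_t = x[:, t, :]
            gx = x_t @ self.w_x + self.bias
            gh = h @ self.w_h
            z = (gx[:, :hid] + gh[:, :hid]).sigmoid()
            r = (gx[:, hid:2 * hid] + gh[:, hid:2 * hid]).sigmoid()
            n = (gx[:, 2 * hid:] + r * gh[:, 2 * hid:]).tanh()
            h = z * h + (1.0 - z) * n
        return h


class SelfAttention(Module):
    """Single-head dot-product self-attention over scalar feature tokens.

    Each entry of the input feature vector is a token; learned affine maps
    embed tokens into key/query space (dimension ``d_k``) and value space
    (dimension ``d_v``).  Attention output is mean-pooled over tokens.
    """

    def __init__(self, d_k: int, d_v: int, rng: np.random.Generator):
        self.d_k = d_k
        self.w_q = Parameter(_glorot(rng, (1, d_k), 1, d_k))
        self.b_q = Parameter(np.zeros(d_k), decay=False)
        self.w_k = Parameter(_glorot(rng, (1, d_k), 1, d_k))
        self.b_k = Parameter(np.zeros(d_k), decay=False)
        self.w_v = Parameter(_glorot(rng, (1, d_v), 1, d_v))
        self.b_v = Parameter(np.zeros(d_v), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        batch, n_tokens = x.data.shape
        tokens = x.reshape(batch * n_tokens, 1)
        q = (tokens @ self.w_q + self.b_q).reshape(batch, n_tokens, -1)
        k = (tokens @ self.w_k + self.b_k).reshape(batch, n_tokens, -1)
        v = (tokens @ self.w_v + self.b_v).reshape(batch, n_tokens, -1)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.d_k))
        weights = softmax(scores, axis=-1)
        attended = weights @ v            # (batch, n_tokens, d_v)
        return attended.mean(axis=1)      # pooled over tokens


class Adam:
    """Adam with coupled L2 regularization on weight parameters."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 l2_factor: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2_factor = l2_factor
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            grad = p.grad
            if self.l2_factor and p.decay:
                grad = grad + self.l2_factor * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad ** 2
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
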