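"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the spectral regression networks need:
broadcast arithmetic, (batched) matrix multiplication, reductions, shape
manipulation, elementwise nonlinearities, stable softmax, windowed max
pooling and 1-D convolution.  Gradients are accumulated by topological-order
backpropagation from a scalar loss.  The engine is validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "max_pool1d", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad=None):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = (any(p.requires_grad for p in out._parents)
                             if requires_grad is None else requires_grad)
        if out.requires_grad:
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad):
            self._accumulate(grad)
            other._accumulate(grad)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            self._accumulate(grad * other.data)
            other._accumulate(grad * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(grad):
            self._accumulate(-grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)

        def backward(grad):
            self._accumulate(grad / other.data)
            other._accumulate(-grad * self.data / other.data ** 2)

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        def backward(grad):
            self._accumulate(grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward needs >= 2-D operands")
            self._accumulate(grad @ np.swapaxes(b, -1, -2))
            other._accumulate(np.swapaxes(a, -1, -2) @ grad)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions and shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        elif isinstance(axis, tuple):
            count = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            count = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(grad):
            self._accumulate(grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inverse = np.argsort(axes)

        def backward(grad):
            self._accumulate(grad.transpose(inverse))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, index):
        def backward(grad):
            full = np.zeros_like(self.data)
            np.add.at(full, index, grad)
            self._accumulate(full)

        return self._make(self.data[index], (self,), backward)

    def flip(self, axis: int):
        def backward(grad):
            self._accumulate(np.flip(grad, axis=axis))

        return self._make(np.flip(self.data, axis=axis), (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad):
            self._accumulate(grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad):
            self._accumulate(grad * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            self._accumulate(grad * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            self._accumulate(grad * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(grad):
            self._accumulate(grad / self.data)

        return self._make(np.log(self.data), (self,), backward)


# --------------------------------------------------------------------------
# Free functions
# --------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * grad.ndim
            index[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(index)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtracted as a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def max_pool1d(x: Tensor, size: int) -> Tensor:
    """Windowed max over the last axis, stride = window, floor semantics."""
    *lead, length = x.data.shape
    n_windows = length // size
    if n_windows < 1:
        raise ValueError(f"axis of length {length} too short for pool size {size}")
    trimmed = x[..., : n_windows * size]
    windows = trimmed.reshape(*lead, n_windows, size)

    data = windows.data
    arg = data.argmax(axis=-1)
    onehot = np.eye(size)[arg]  # (..., n_windows, size)

    def backward(grad):
        windows._accumulate(grad[..., None] * onehot)

    return Tensor._make(data.max(axis=-1), (windows,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, pad: int) -> Tensor:
    """'Same'-style 1-D convolution (cross-correlation).

    ``x``: (batch, in_channels, length); ``weight``: (out_channels,
    in_channels, kernel); ``bias``: (out_channels,).  Output length is
    ``length + 2*pad - kernel + 1``.
    """
    batch, c_in, length = x.data.shape
    c_out, c_in_w, kernel = weight.data.shape
    if c_in != c_in_w:
        raise ValueError("channel mismatch in conv1d")
    padded = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    out_len = length + 2 * pad - kernel + 1

    # im2col: (batch, out_len, c_in * kernel)
    strides = padded.strides
    windows = np.lib.stride_tricks.as_strided(
        padded, shape=(batch, out_len, c_in, kernel),
        strides=(strides[0], strides[2], strides[1], strides[2]),
        writeable=False,
    )
    cols = windows.reshape(batch, out_len, c_in * kernel)
    w_mat = weight.data.reshape(c_out, c_in * kernel)
    out_data = cols @ w_mat.T + bias.data  # (batch, out_len, c_out)
    out_data = out_data.transpose(0, 2, 1)

    def backward(grad):
        g = grad.transpose(0, 2, 1)  # (batch, out_len, c_out)
        bias._accumulate(g.sum(axis=(0, 1)))
        weight._accumulate(
            np.einsum("blo,blk->ok", g, cols).reshape(weight.data.shape))
        g_cols = g @ w_mat  # (batch, out_len, c_in * kernel)
        g_windows = g_cols.reshape(batch, out_len, c_in, kernel)
        g_padded = np.zeros_like(padded)
        for k in range(kernel):
            g_padded[:, :, k:k + out_len] += g_windows[:, :, :, k].transpose(0, 2, 1)
        x._accumulate(g_padded[:, :, pad:pad + length] if pad else g_padded)

    return Tensor._make(out_data, (x, weight, bias), backward)
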