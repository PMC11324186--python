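"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express the encoding models in this package
(temporal/2-D convolutions via unfold + einsum, batch normalization,
sigmoid/ReLU nonlinearities, exponential smoothing kernels built from learned
time constants) and to optimize them jointly with the filter parameters using
an adaptive-moment gradient method.  Everything is double precision and
CPU-only, which is the scale these models run at.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "AdamW", "sigmoid", "relu", "leaky_relu", "concatenate", "einsum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad=False, _parents=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = _parents

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents),
                     _parents=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = backward
        return out

    def exp(self):
        val = np.exp(self.data)
        out = self._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * val)
        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = backward
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, dtype=float)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).reshape(self.data.shape))
        out._backward = backward
        return out

    def transpose(self, axes):
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.asarray(g).transpose(inv))
        out._backward = backward
        return out

    def __getitem__(self, key):
        out = self._make(self.data[key], (self,), None)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)
        out._backward = backward
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            g = np.asarray(g, dtype=float)
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = backward
        return out

    # -- structured ops -------------------------------------------------------
    def unfold(self, size: int):
        """Sliding windows along the last axis: (..., T) -> (..., T-size+1, size)."""
        from numpy.lib.stride_tricks import sliding_window_view

        val = sliding_window_view(self.data, size, axis=-1).copy()
        out = self._make(val, (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, dtype=float)
            full = np.zeros_like(self.data)
            t_out = g.shape[-2]
            for l in range(size):
                full[..., l:l + t_out] += g[..., :, l]
            self._accum(full)
        out._backward = backward
        return out

    def pad_left_replicate(self, n: int):
        """Left-pad the last axis with ``n`` copies of its first sample."""
        first = self.data[..., :1]
        val = np.concatenate([np.repeat(first, n, axis=-1), self.data], axis=-1)
        out = self._make(val, (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, dtype=float)
            full = g[..., n:].copy()
            full[..., 0] += g[..., :n].sum(axis=-1)
            self._accum(full)
        out._backward = backward
        return out

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


# -- free functions -----------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = x._make(val, (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(g * val * (1.0 - val))
    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = x._make(np.maximum(x.data, 0.0), (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))
    out._backward = backward
    return out


def leaky_relu(x: Tensor, negative_slope=0.1) -> Tensor:
    slope = np.where(x.data > 0, 1.0, negative_slope)
    out = x._make(x.data * slope, (x,), None)

    def backward(g):
        if x.requires_grad:
            x._accum(g * slope)
    out._backward = backward
    return out


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    val = np.concatenate([t.data for t in tensors], axis=axis)
    out = tensors[0]._make(val, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        g = np.asarray(g, dtype=float)
        start = 0
        for t, n in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            if t.requires_grad:
                t._accum(g[tuple(sl)])
            start += n
    out._backward = backward
    return out


def einsum(subscripts: str, *operands) -> Tensor:
    """Differentiable einsum for patterns without intra-operand diagonals and
    where every operand index appears in the output or another operand."""
    operands = [Tensor.as_tensor(t) for t in operands]
    in_subs, out_sub = subscripts.replace(" ", "").split("->")
    in_subs = in_subs.split(",")
    val = np.einsum(subscripts, *[t.data for t in operands])
    out = operands[0]._make(val, tuple(operands), None)

    def backward(g):
        g = np.asarray(g, dtype=float)
        for i, t in enumerate(operands):
            if not t.requires_grad:
                continue
            others = [operands[j].data for j in range(len(operands)) if j != i]
            other_subs = [in_subs[j] for j in range(len(operands)) if j != i]
            spec = ",".join([out_sub] + other_subs) + "->" + in_subs[i]
            t._accum(np.einsum(spec, g, *others))
    out._backward = backward
    return out


class AdamW(object):
    """Adaptive-moment optimizer (decoupled weight decay; default decay 0)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data *= (1 - self.lr * self.weight_decay)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
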