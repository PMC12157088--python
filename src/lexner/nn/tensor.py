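"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the sequence-labelling model needs:
elementwise arithmetic with broadcasting, 2-D matrix products, the usual
nonlinearities, fused softmax / log-sum-exp / layer-norm, concatenation,
and advanced indexing (which doubles as embedding lookup).  Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent, fn) where fn maps the output gradient to the
        # parent's gradient contribution
        self._parents: list[tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = []

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data: np.ndarray, links: Sequence[tuple["Tensor", Callable]]) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p, _ in links):
            out = Tensor(data, requires_grad=True)
            out._parents = [(p, fn) for p, fn in links if p.requires_grad]
            return out
        return Tensor(data)

    # -- basic info -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        return Tensor._make(self.data.T, [(self, lambda g: g.T)])

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        return Tensor._make(
            self.data + other.data,
            [(self, lambda g: _unbroadcast(g, self.shape)),
             (other, lambda g: _unbroadcast(g, other.shape))],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        return Tensor._make(
            self.data * other.data,
            [(self, lambda g: _unbroadcast(g * other.data, self.shape)),
             (other, lambda g: _unbroadcast(g * self.data, other.shape))],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return Tensor._make(
            self.data / other.data,
            [(self, lambda g: _unbroadcast(g / other.data, self.shape)),
             (other, lambda g: _unbroadcast(-g * self.data / other.data ** 2, other.shape))],
        )

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        return Tensor._make(
            self.data @ other.data,
            [(self, lambda g: g @ other.data.T),
             (other, lambda g: self.data.T @ g)],
        )

    def __getitem__(self, idx) -> "Tensor":
        def back(g, idx=idx):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            return buf

        return Tensor._make(self.data[idx], [(self, back)])

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.shape).copy()

        return Tensor._make(out, [(self, back)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        out = np.log(np.exp(self.data - m).sum(axis=axis, keepdims=True)) + m
        soft = np.exp(self.data - out)
        if not keepdims:
            out = np.squeeze(out, axis=axis)

        def back(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            return g * soft

        return Tensor._make(out, [(self, back)])

    # -- nonlinearities -------------------------------------------------------

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self) -> "Tensor":
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out ** 2))])

    def sigmoid(self) -> "Tensor":
        out = expit(self.data)
        return Tensor._make(out, [(self, lambda g: g * out * (1.0 - out))])

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            return out * (g - (g * out).sum(axis=axis, keepdims=True))

        return Tensor._make(out, [(self, back)])

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        return Tensor._make(self.data.reshape(*shape), [(self, lambda g: g.reshape(orig))])

    # -- backward pass --------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    links = []
    offset = 0
    for t in tensors:
        size = t.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offset, offset + size)
        links.append((t, lambda g, sl=tuple(sl): g[sl]))
        offset += size
    return Tensor._make(data, links)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalisation with affine rescaling (last axis)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def back_x(g):
        dxhat = g * gamma.data
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )

    def back_gamma(g):
        return _unbroadcast(g * xhat, gamma.shape)

    def back_beta(g):
        return _unbroadcast(g, beta.shape)

    return Tensor._make(out, [(x, back_x), (gamma, back_gamma), (beta, back_beta)])


class Parameter(Tensor):
    """A leaf tensor that optimizers update."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
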