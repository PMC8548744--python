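"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray`` and records, for each operation, closures that map the output
gradient to contributions for each input. :meth:`Tensor.backward` walks the
tape in reverse topological order. Only the operations the recurrent cells,
the dense feature extractor and the softmax classifier need are provided.

Gradients produced here are cross-checked against central finite
differences in the test suite and by the ``gradcheck`` command, which is
the contract that keeps this engine honest.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "zeros",
    "no_grad",
    "is_grad_enabled",
    "sigmoid",
    "tanh",
    "log",
    "exp",
    "softmax",
    "clip_min",
    "concat",
    "transpose",
    "matmul",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Context manager disabling tape recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum dims that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape entry.

    Parameters with ``requires_grad=True`` are graph leaves; intermediate
    results inherit the flag from their inputs. After ``backward`` every
    node that requires grad holds its gradient in ``.grad``.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(value, parents, vjps) -> "Tensor":
        out = Tensor(value)
        if _GRAD_ENABLED:
            keep = [
                (p, v) for p, v in zip(parents, vjps) if p.requires_grad
            ]
            if keep:
                out.requires_grad = True
                out._parents = tuple(p for p, _ in keep)
                out._vjps = tuple(v for _, v in keep)
        return out

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor({self.value!r}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.value + other.value,
            (self, other),
            (
                lambda g, s=self.value.shape: _unbroadcast(g, s),
                lambda g, s=other.value.shape: _unbroadcast(g, s),
            ),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.value - other.value,
            (self, other),
            (
                lambda g, s=self.value.shape: _unbroadcast(g, s),
                lambda g, s=other.value.shape: _unbroadcast(-g, s),
            ),
        )

    def __rsub__(self, other):
        return as_tensor(other).__sub__(self)

    def __neg__(self):
        return Tensor._make(-self.value, (self,), (lambda g: -g,))

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.value * other.value,
            (self, other),
            (
                lambda g, o=other.value, s=self.value.shape: _unbroadcast(g * o, s),
                lambda g, o=self.value, s=other.value.shape: _unbroadcast(g * o, s),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.value / other.value,
            (self, other),
            (
                lambda g, o=other.value, s=self.value.shape: _unbroadcast(g / o, s),
                lambda g, a=self.value, o=other.value, s=other.value.shape: _unbroadcast(
                    -g * a / (o * o), s
                ),
            ),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.value, other.value
        return Tensor._make(
            a @ b,
            (self, other),
            (
                lambda g, b=b: g @ b.T,
                lambda g, a=a: a.T @ g,
            ),
        )

    def __getitem__(self, key):
        def vjp(g, key=key, shape=self.value.shape):
            out = np.zeros(shape)
            out[key] = g
            return out

        return Tensor._make(self.value[key], (self,), (vjp,))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def vjp(g, axis=axis, keepdims=keepdims, shape=self.value.shape):
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), (vjp,))

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            self.value.reshape(shape),
            (self,),
            (lambda g, s=self.value.shape: g.reshape(s),),
        )

    # -- backward -------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` into every reachable leaf."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.value.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: sequences can be long
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def zeros(*shape, requires_grad: bool = False) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=requires_grad)


# -- elementwise nonlinearities ------------------------------------------------
def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    v = np.where(x.value >= 0, 1.0 / (1.0 + np.exp(-x.value)),
                 np.exp(x.value) / (1.0 + np.exp(x.value)))
    return Tensor._make(v, (x,), (lambda g, v=v: g * v * (1.0 - v),))


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    v = np.tanh(x.value)
    return Tensor._make(v, (x,), (lambda g, v=v: g * (1.0 - v * v),))


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._make(np.log(x.value), (x,), (lambda g, v=x.value: g / v,))


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    v = np.exp(x.value)
    return Tensor._make(v, (x,), (lambda g, v=v: g * v,))


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient passes where x > lo (subgradient 0 below)."""
    x = as_tensor(x)
    mask = x.value > lo
    return Tensor._make(np.maximum(x.value, lo), (x,), (lambda g, m=mask: g * m,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    z = x.value - x.value.max(axis=axis, keepdims=True)
    e = np.exp(z)
    v = e / e.sum(axis=axis, keepdims=True)

    def vjp(g, v=v, axis=axis):
        return v * (g - (g * v).sum(axis=axis, keepdims=True))

    return Tensor._make(v, (x,), (vjp,))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    values = [t.value for t in tensors]
    out = np.concatenate(values, axis=axis)
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            return g[tuple(idx)]

        return vjp

    return Tensor._make(out, tuple(tensors), tuple(make_vjp(i) for i in range(len(tensors))))


def transpose(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._make(x.value.T, (x,), (lambda g: g.T,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return as_tensor(a) @ as_tensor(b)


def collect_parameters(obj) -> list[Tensor]:
    """Flatten any nesting of Tensors / lists / dicts into a parameter list."""
    out: list[Tensor] = []
    _collect(obj, out)
    return out


def _collect(obj, out: list) -> None:
    if isinstance(obj, Tensor):
        if obj.requires_grad:
            out.append(obj)
    elif isinstance(obj, dict):
        for v in obj.values():
            _collect(v, out)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _collect(v, out)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
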