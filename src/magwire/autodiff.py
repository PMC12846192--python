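"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small per-point MLPs with batch
normalisation, cross-attention and max-pooling; this module provides just
the operations they need, with full broadcasting support, so the whole
model fits in plain numpy.  Gradients are accumulated by topological
traversal of the op graph recorded during the forward pass.

All ops accept ``Tensor`` or raw array-likes; raw inputs are treated as
constants.  Shapes may be batched arbitrarily (e.g. ``(B, N, D)``);
``matmul`` maps to :func:`numpy.matmul` semantics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "leaky_relu",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient and a record of how it was made."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")
    __array_priority__ = 100  # so ndarray.__add__ defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # list of (parent Tensor, fn upstream_grad -> grad wrt parent)
        self._parents: list = []

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents) -> "Tensor":
        out = Tensor(data)
        live = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        if live:
            out._parents = live
            out.requires_grad = True
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        d = self.data
        return self._make(d**p, [(self, lambda g: g * p * d ** (p - 1.0))])

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def ga(g):
            if b.ndim == 1:
                return _unbroadcast(np.multiply.outer(g, b) if a.ndim > 1 else g * b, a.shape)
            return _unbroadcast(np.matmul(g, np.swapaxes(b, -1, -2)), a.shape)

        def gb(g):
            if a.ndim == 1:
                return _unbroadcast(np.multiply.outer(a, g), b.shape)
            return _unbroadcast(np.matmul(np.swapaxes(a, -1, -2), g), b.shape)

        return self._make(np.matmul(a, b), [(self, ga), (other, gb)])

    # -- elementwise ---------------------------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return self._make(out, [(self, lambda g: g * out)])

    def log(self):
        d = self.data
        return self._make(np.log(d), [(self, lambda g: g / d)])

    def sqrt(self):
        return self**0.5

    def abs(self):
        d = self.data
        return self._make(np.abs(d), [(self, lambda g: g * np.sign(d))])

    def tanh(self):
        out = np.tanh(self.data)
        return self._make(out, [(self, lambda g: g * (1.0 - out**2))])

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        d = self.data

        def grad(g):
            if axis is None:
                return np.broadcast_to(g, d.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, d.shape).copy()

        return self._make(d.sum(axis=axis, keepdims=keepdims), [(self, grad)])

    def mean(self, axis=None, keepdims: bool = False):
        d = self.data
        n = d.size if axis is None else np.prod(
            [d.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def _extremum(self, axis: int, keepdims: bool, mode: str):
        d = self.data
        fn = np.max if mode == "max" else np.min
        arg = np.argmax(d, axis=axis) if mode == "max" else np.argmin(d, axis=axis)
        out = fn(d, axis=axis, keepdims=keepdims)

        def grad(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            mask = np.zeros_like(d)
            np.put_along_axis(mask, np.expand_dims(arg, axis), 1.0, axis=axis)
            return mask * np.broadcast_to(g2, d.shape)

        return self._make(out, [(self, grad)])

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routed to the first maximiser."""
        return self._extremum(axis, keepdims, "max")

    def min(self, axis: int, keepdims: bool = False):
        return self._extremum(axis, keepdims, "min")

    # -- shape ---------------------------------------------------------------

    def reshape(self, *shape):
        d = self.data
        return self._make(d.reshape(*shape), [(self, lambda g: g.reshape(d.shape))])

    def swapaxes(self, a: int, b: int):
        return self._make(
            np.swapaxes(self.data, a, b), [(self, lambda g: np.swapaxes(g, a, b))]
        )

    def broadcast_to(self, shape):
        d = self.data
        return self._make(
            np.broadcast_to(d, shape).copy(), [(self, lambda g: _unbroadcast(g, d.shape))]
        )

    def __getitem__(self, idx):
        d = self.data

        def grad(g):
            out = np.zeros_like(d)
            np.add.at(out, idx, g)
            return out

        return self._make(d[idx], [(self, grad)])

    # -- backward ------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p, _ in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    parents = []
    for i, t in enumerate(tensors):
        lo, hi = offsets[i], offsets[i + 1]

        def grad(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, grad))
    return Tensor._make(np.concatenate(datas, axis=axis), parents)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    x = Tensor._wrap(x)
    d = x.data
    scale = np.where(d >= 0, 1.0, negative_slope)
    return Tensor._make(d * scale, [(x, lambda g: g * scale)])


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    x = Tensor._wrap(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
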