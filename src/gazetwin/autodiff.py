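"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients through the recorded
graph.  The op set is exactly what the transformer encoder/decoder stack and
the scanpath losses need: broadcast arithmetic, batched matmul, exp/log/
tanh/relu/abs/sqrt, reductions, reshape/transpose/slice/concat, softmax,
embedding gather, and clipping.  Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_bw")

    # make numpy defer to the reflected operators instead of elementwise
    # object broadcasting when an ndarray is the left operand
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _prev=(), _bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self.grad: np.ndarray | None = None
        self._prev = _prev if self.requires_grad else ()
        self._bw = _bw if self.requires_grad else None

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> np.ndarray:
        return self.data

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        out = Tensor(a.data + b.data, _prev=(a, b),
                     _bw=lambda g: (a._accum(_unbroadcast(g, a.shape)) if a.requires_grad else None,
                                    b._accum(_unbroadcast(g, b.shape)) if b.requires_grad else None))
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.data, _prev=(a,),
                      _bw=lambda g: a._accum(-g) if a.requires_grad else None)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        out = Tensor(a.data * b.data, _prev=(a, b),
                     _bw=lambda g: (a._accum(_unbroadcast(g * b.data, a.shape)) if a.requires_grad else None,
                                    b._accum(_unbroadcast(g * a.data, b.shape)) if b.requires_grad else None))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = Tensor._wrap(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p
        def bw(g, a=a, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))
        return Tensor(out_data, _prev=(a,), _bw=bw)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data @ b.data
        def bw(g, a=a, b=b):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))
        return Tensor(out_data, _prev=(a, b), _bw=bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor(out_data, _prev=(a,),
                      _bw=lambda g: a._accum(g * out_data) if a.requires_grad else None)

    def log(self):
        a = self
        return Tensor(np.log(a.data), _prev=(a,),
                      _bw=lambda g: a._accum(g / a.data) if a.requires_grad else None)

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor(out_data, _prev=(a,),
                      _bw=lambda g: a._accum(g * (1.0 - out_data ** 2)) if a.requires_grad else None)

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor(a.data * mask, _prev=(a,),
                      _bw=lambda g: a._accum(g * mask) if a.requires_grad else None)

    def abs(self):
        a = self
        sign = np.sign(a.data)
        return Tensor(np.abs(a.data), _prev=(a,),
                      _bw=lambda g: a._accum(g * sign) if a.requires_grad else None)

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only where unclipped (subgradient)."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)
        return Tensor(np.clip(a.data, lo, hi), _prev=(a,),
                      _bw=lambda g: a._accum(g * mask) if a.requires_grad else None)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)
        def bw(g, a=a, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else
                         np.full(a.shape, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy())
        return Tensor(out_data, _prev=(a,), _bw=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(a.data.reshape(shape), _prev=(a,),
                      _bw=lambda g: a._accum(g.reshape(a.shape)) if a.requires_grad else None)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(a.data.transpose(axes), _prev=(a,),
                      _bw=lambda g: a._accum(g.transpose(inv)) if a.requires_grad else None)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]
        def bw(g, a=a, idx=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor(out_data, _prev=(a,), _bw=bw)


# ---------------------------------------------------------------------------
# Functional ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor(out_data, _prev=tuple(tensors), _bw=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = Tensor._wrap(x)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)
    def bw(g, a=a, axis=axis):
        if a.requires_grad:
            dot = (out_data * g).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))
    return Tensor(out_data, _prev=(a,), _bw=bw)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``weight[ids]`` with scatter-add gradient."""
    ids = np.asarray(ids, dtype=np.intp)
    out_data = weight.data[ids]
    def bw(g, weight=weight, ids=ids):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.ravel(), g.reshape(-1, g.shape[-1]))
            weight._accum(full)
    return Tensor(out_data, _prev=(weight,), _bw=bw)


def where_const(mask: np.ndarray, x: Tensor, other: float) -> Tensor:
    """``mask ? x : other`` with a constant fallback value."""
    a = Tensor._wrap(x)
    mask = np.asarray(mask, dtype=bool)
    out_data = np.where(mask, a.data, other)
    def bw(g, a=a):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.shape))
    return Tensor(out_data, _prev=(a,), _bw=bw)
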