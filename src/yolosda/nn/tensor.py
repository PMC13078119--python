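"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd tradition: each :class:`Tensor`
wraps an ``ndarray``; differentiable operations record a closure that
propagates the upstream gradient to their inputs. The op set is deliberately
minimal — convolution, normalisation and resampling live in
:mod:`yolosda.nn.ops` as fused primitives with hand-written backwards, while
elementwise arithmetic, reductions and shape manipulation live here.

Gradients are accumulated into ``.grad`` (a plain ndarray) by
:meth:`Tensor.backward`, which topologically sorts the recorded graph.
"""

from __future__ import annotations

import contextlib

import numpy as np

from . import profile

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "concat", "stack"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the ``with`` block (eval/inference)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer to our reflected operators (ndarray + Tensor etc.)
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        """Create a result node; record the tape only when grads are on."""
        req = _grad_enabled and any(
            isinstance(p, Tensor) and p.requires_grad for p in parents
        )
        out = Tensor(data, requires_grad=req)
        if req:
            out._backward = backward
            out._prev = tuple(p for p in parents if isinstance(p, Tensor))
        return out

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        work = [(self, False)]
        while work:  # iterative postorder; deep nets overflow recursion
            node, processed = work.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            work.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    work.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the closure so intermediate buffers can be reclaimed
                node._backward = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = a.data + bd

        def backward(g):
            a._accum(_unbroadcast(g, a.data.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = a.data * bd

        def backward(g):
            a._accum(_unbroadcast(g * bd, a.data.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return self.reciprocal() * other

    def reciprocal(self):
        a = self
        out_data = 1.0 / a.data

        def backward(g):
            a._accum(-g * out_data * out_data)

        return Tensor._make(out_data, (a,), backward)

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (a,), backward)

    def atan(self):
        a = self
        out_data = np.arctan(a.data)

        def backward(g):
            a._accum(g / (1.0 + a.data * a.data))

        return Tensor._make(out_data, (a,), backward)

    # -- activations -------------------------------------------------------
    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = a.data * mask

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(out_data, (a,), backward)

    def relu6(self):
        a = self
        mask = (a.data > 0) & (a.data < 6.0)
        out_data = np.clip(a.data, 0.0, 6.0)

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(out_data, (a,), backward)

    def silu(self):
        a = self
        sig = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
        out_data = a.data * sig

        def backward(g):
            a._accum(g * sig * (1.0 + a.data * (1.0 - sig)))

        return Tensor._make(out_data, (a,), backward)

    # -- elementwise min/max ----------------------------------------------
    def maximum(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = np.maximum(a.data, bd)
        amask = a.data >= bd

        def backward(g):
            a._accum(_unbroadcast(g * amask, a.data.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * (~amask), b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    def minimum(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = np.minimum(a.data, bd)
        amask = a.data <= bd

        def backward(g):
            a._accum(_unbroadcast(g * amask, a.data.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * (~amask), b.data.shape))

        return Tensor._make(out_data, (a, b), backward)

    def clip(self, lo, hi):
        return self.maximum(lo).minimum(hi)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = a.data.reshape(shape)

        def backward(g):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        out_data = a.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(out_data, (a,), backward)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = a.data @ bd
        if profile.active():
            profile.add_matmul(out_data.size * a.data.shape[-1])

        def backward(g):
            ga = g @ np.swapaxes(bd, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out_data, (a, b), backward)


def concat(tensors, axis=0) -> Tensor:
    """Differentiable concatenation along ``axis``."""
    datas = [_as_array(t) for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if isinstance(t, Tensor) and t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0) -> Tensor:
    datas = [_as_array(t) for t in tensors]
    out_data = np.stack(datas, axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if isinstance(t, Tensor) and t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
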