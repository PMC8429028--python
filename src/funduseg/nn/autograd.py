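"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape-based engine sized for CPU-scale segmentation networks:
tensors wrap float64/float32 numpy arrays, every differentiable op records
a backward closure, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations the segmentation network needs are
implemented (elementwise arithmetic, batched matmul, softmax, reductions,
reshapes and concatenation); convolution, pooling, normalisation and
upsampling live in :mod:`funduseg.nn.layers` as modules built on the same
tape mechanism via :func:`from_op`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "from_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed the recursion limit
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        _attach(out, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        _attach(out, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data)
        _attach(out, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """Batched matrix product over the last two axes."""
        out = Tensor(np.matmul(self.data, other.data))
        _attach(out, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        _attach(out, (self,))
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y)
        _attach(out, (self,))

        def bwd(g):
            self._accumulate(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data))
        _attach(out, (self,))

        def bwd(g):
            self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y)
        _attach(out, (self,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bwd
        return out

    # -- reductions and reshapes ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        _attach(out, (self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        _attach(out, (self,))

        def bwd(g):
            self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out

    def swap_last_axes(self) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, -1, -2))
        _attach(out, (self,))

        def bwd(g):
            self._accumulate(np.swapaxes(g, -1, -2))

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A tensor registered as trainable state of a module."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _attach(out: Tensor, parents: tuple[Tensor, ...]):
    needs = any(p.requires_grad for p in parents)
    out.requires_grad = needs
    if needs:
        out._parents = parents


def from_op(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Build a tape node for an op implemented outside the Tensor class."""
    out = Tensor(data)
    _attach(out, parents)
    if out.requires_grad:
        out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    out_data = np.concatenate(datas, axis=axis)

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad:
                t._accumulate(g[tuple(sl)])
            start += s

    return from_op(out_data, tuple(tensors), bwd)
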