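"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the recurrent ensemble members: broadcast-aware
elementwise arithmetic, matmul, the usual activations, reductions, column
slicing, concatenation, and embedding-row gather.  Gradients are accumulated
into ``Tensor.grad`` ndarrays by :meth:`Tensor.backward`, which walks a
topologically sorted tape.  Everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def pow(self, exponent: float) -> "Tensor":
        a = self
        out_data = a.data**exponent

        def backward(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return self._make(out_data, (a,), backward)

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    # -- activations -------------------------------------------------------
    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * (1.0 - out_data**2)))

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data * (1.0 - out_data)))

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0
        return self._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def softplus(self) -> "Tensor":
        a = self
        out_data = np.logaddexp(0.0, a.data)
        sig = 1.0 / (1.0 + np.exp(-a.data))
        return self._make(out_data, (a,), lambda g: a._accum(g * sig))

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self) -> "Tensor":
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        a = self
        out_data = a.data[:, start:stop]

        def backward(g):
            full = np.zeros_like(a.data)
            full[:, start:stop] = g
            a._accum(full)

        return self._make(out_data, (a,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(g[tuple(idx)])

        return Tensor._make(out_data, tuple(tensors), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows (embedding lookup); gradient scatter-adds."""
        a = self
        indices = np.asarray(indices)
        out_data = a.data[indices]

        def backward(g):
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            np.add.at(a.grad, indices, g)

        return self._make(out_data, (a,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    """Wrap an array as a trainable tensor."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
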