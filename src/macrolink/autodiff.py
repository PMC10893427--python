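"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the graph-attention encoder and the two MLP heads:
broadcast-aware add/mul, (batched) matmul, reshape/concat/gather, the
activations (ReLU, leaky ReLU, sigmoid), softmax, log, and reductions.
Gradients are accumulated on a tape and released by :meth:`Tensor.backward`;
correctness is established against central finite differences in the test
suite rather than asserted here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape helpers -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._node(self.data[idx], (self,), bw)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        return Tensor._node(self.data / other.data, (self, other), bw)

    def matmul(self, other) -> "Tensor":
        """Matrix product; supports numpy's batched semantics (stacked matrices)."""
        other = Tensor._lift(other)

        def bw(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._node(self.data @ other.data, (self, other), bw)

    __matmul__ = matmul

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accum(g * factor)

        return Tensor._node(self.data * factor, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor._node(out, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._node(np.clip(self.data, lo, hi), (self,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` with an analytic backward."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - dot))

    return Tensor._node(out, (x,), bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``; backward splits the gradient."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._node(np.concatenate(datas, axis=axis), tuple(tensors), bw)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor by integer index (with repeats allowed)."""
    idx = np.asarray(idx, dtype=np.int64)

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accum(full)

    return Tensor._node(x.data[idx], (x,), bw)
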