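"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32/float64 ndarray and records the operations
applied to it; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients. Gradients are kept on *every* node of the
graph (not only leaves), which is what the per-scale class-activation maps
need: they read the gradient of a class logit with respect to intermediate
backbone feature maps.

Only the operations the OCT classifier needs are implemented; each op is a
closed-form vector-Jacobian product, checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        dtype = np.float64 if arr.dtype == np.float64 else np.float32
        self.data = np.asarray(arr, dtype=dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        t = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            t._parents = parents
            t._backward = backward
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming array may be shared with another node's grad
            if grad.dtype == self.data.dtype:
                self.grad = grad.copy()
            else:
                self.grad = grad.astype(self.data.dtype)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward, rq)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward, rq)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = as_tensor(other)
        rq = self.requires_grad or other.requires_grad
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), backward, rq)

    # -- elementwise nonlinearities ------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- reductions & shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old_shape))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(int(np.argsort(axes)[i]) for i in range(len(axes)))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # -- composite helpers ---------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)  # detached max
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def l2_normalize(self, axis: int = -1, eps: float = 1e-12):
        norm_sq = (self * self).sum(axis=axis, keepdims=True)
        return self * (norm_sq + eps) ** -0.5

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # Python scalars must not promote float32 graphs to float64
        return Tensor(np.float32(x))
    return Tensor(x)
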