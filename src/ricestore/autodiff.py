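"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the small sequence models in this package:
a :class:`Tensor` wrapping an ndarray, the elementwise/matrix operations the
model needs, broadcasting-aware gradients, and an Adam optimizer with global
gradient-norm clipping.  Everything is float64 and CPU-only by design.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "clip_grad_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_sink")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar unless *grad* given) output."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the graph
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._grad_sink = grads  # type: ignore[attr-defined]
                try:
                    node._backward(g)
                finally:
                    del node._grad_sink  # type: ignore[attr-defined]
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # The closures below route gradients through the dict owned by the
    # running backward() call (attached temporarily as _grad_sink).

    def _route(self, pairs: list[tuple["Tensor", np.ndarray]]) -> None:
        sink = getattr(self, "_grad_sink")
        for parent, g in pairs:
            if parent.requires_grad:
                if parent._parents or parent._backward is not None:
                    key = id(parent)
                    sink[key] = g if key not in sink else sink[key] + g
                else:
                    parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            out._route([(self, _unbroadcast(g, self.shape)),
                        (other, _unbroadcast(g, other.shape))])

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            out._route([(self, -g)])

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            out._route([(self, _unbroadcast(g * other.data, self.shape)),
                        (other, _unbroadcast(g * self.data, other.shape))])

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            out._route([
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ])

        out = self._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            out._route([(self, g * exponent * self.data ** (exponent - 1))])

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            out._route([(self, _unbroadcast(ga, a.shape)),
                        (other, _unbroadcast(gb, b.shape))])

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise functions -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            out._route([(self, g * out_data)])

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward(g):
            out._route([(self, g / self.data)])

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            out._route([(self, g * 0.5 / out_data)])

        out = self._make(out_data, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            out._route([(self, g * (1.0 - out_data**2))])

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            out._route([(self, g * out_data * (1.0 - out_data))])

        out = self._make(out_data, (self,), backward)
        return out

    def sin(self):
        def backward(g):
            out._route([(self, g * np.cos(self.data))])

        out = self._make(np.sin(self.data), (self,), backward)
        return out

    def cos(self):
        def backward(g):
            out._route([(self, -g * np.sin(self.data))])

        out = self._make(np.cos(self.data), (self,), backward)
        return out

    def abs(self):
        def backward(g):
            out._route([(self, g * np.sign(self.data))])

        out = self._make(np.abs(self.data), (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward(g):
            out._route([(self, g * mask)])

        out = self._make(self.data * mask, (self,), backward)
        return out

    # -- reductions & shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            out._route([(self, np.broadcast_to(g, self.shape).copy())])

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            out._route([(self, np.swapaxes(g, a, b))])

        out = self._make(out_data, (self,), backward)
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            out._route([(self, g.reshape(old))])

        out = self._make(out_data, (self,), backward)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            out._route([(self, full)])

        out = self._make(out_data, (self,), backward)
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        pairs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pairs.append((t, g[tuple(sl)]))
        out._route(pairs)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is at most *max_norm*."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total


class Adam:
    """Adaptive-moment gradient descent over a list of :class:`Tensor`."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
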