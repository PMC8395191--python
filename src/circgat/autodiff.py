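"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the graph-attention encoder and the pair
classifier need: dense affine maps, row gather / segment scatter-add (the
message-passing primitives), the usual elementwise nonlinearities, and
reductions. Everything is float64 and fully deterministic.

Gradients follow the standard tape discipline: ``backward()`` on a scalar
output topologically sorts the tape and accumulates ``grad`` on every tensor
created with ``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum", "segment_max_values"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.value))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(x: "Tensor | np.ndarray | float") -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        """Sum gradient g down to the given (possibly broadcast) shape."""
        while g.ndim > len(shape):
            g = g.sum(axis=0)
        for ax, dim in enumerate(shape):
            if dim == 1 and g.shape[ax] != 1:
                g = g.sum(axis=ax, keepdims=True)
        return g.reshape(shape)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.value + other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(self._unbroadcast(g, self.value.shape))
            if other.requires_grad or other._parents:
                other._accumulate(self._unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __sub__(self, other):
        return self + (self._wrap(other) * -1.0)

    def __rsub__(self, other):
        return self._wrap(other) + (self * -1.0)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.value * other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(self._unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad or other._parents:
                other._accumulate(self._unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.value / other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(self._unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    self._unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.value @ other.value, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.value.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.value.T @ g)

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self) -> "Tensor":
        v = np.exp(self.value)
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: self._accumulate(g * v)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.value)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.value))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), computed overflow-free; gradient is sigmoid(x)."""
        v = np.maximum(self.value, 0.0) + np.log1p(np.exp(-np.abs(self.value)))
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: self._accumulate(g / (1.0 + np.exp(-self.value)))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        pos = self.value > 0
        out = Tensor(np.where(pos, self.value, slope * self.value), parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.where(pos, 1.0, slope))
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.value > 0
        v = np.where(pos, self.value, alpha * np.expm1(self.value))
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.where(pos, 1.0, v + alpha))
        return out

    # -- gather / scatter ---------------------------------------------------

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Rows self[idx]; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.value[idx], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.value)
            np.add.at(acc, idx, g)
            self._accumulate(acc)

        out._backward = bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self) -> "Tensor":
        out = Tensor(self.value.sum(), parents=(self,))
        out._backward = lambda g: self._accumulate(np.full_like(self.value, float(g)))
        return out

    def mean_rows(self) -> "Tensor":
        """Mean over axis 0, keeping remaining axes."""
        n = self.value.shape[0]
        out = Tensor(self.value.mean(axis=0), parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g / n, self.value.shape).copy())
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis; gradient splits back."""
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def segment_sum(t: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """out[k] = sum of rows of t where idx == k; the scatter-add primitive."""
    idx = np.asarray(idx, dtype=np.intp)
    acc = np.zeros((n,) + t.value.shape[1:], dtype=np.float64)
    np.add.at(acc, idx, t.value)
    out = Tensor(acc, parents=(t,))
    out._backward = lambda g: t._accumulate(g[idx])
    return out


def segment_max_values(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Per-segment maximum of a plain array (no gradient; softmax shift)."""
    out = np.full((n,) + values.shape[1:], -np.inf)
    np.maximum.at(out, np.asarray(idx, dtype=np.intp), values)
    return out
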