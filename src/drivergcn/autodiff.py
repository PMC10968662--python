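"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations needed by a sparse graph-convolutional
network with an attention-weighted conditional-random-field refinement
layer: dense matrix products, products with a constant sparse matrix,
elementwise arithmetic and nonlinearities, row gathers and segment sums
over edge lists, and reductions.  Everything is float64; gradients are
accumulated by a topological-order backward sweep.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Adam", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def spmm(self, matrix: sp.spmatrix) -> "Tensor":
        """Left-multiply by a constant sparse matrix: out = matrix @ self."""
        matrix = sp.csr_matrix(matrix)
        out = Tensor(matrix @ self.data, parents=(self,))
        mt = matrix.T.tocsr()
        out._backward = lambda g: self._accumulate(mt @ g)
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        scale = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * scale, parents=(self,))
        out._backward = lambda g: self._accumulate(g * scale)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def clip(self, low: float, high: float) -> "Tensor":
        """Clamp values; gradient is zero outside [low, high]."""
        mask = (self.data >= low) & (self.data <= high)
        out = Tensor(np.clip(self.data, low, high), parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- reductions & indexing ---------------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        return self.sum() * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows; backward scatter-adds into the source rows."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accumulate(acc)

        out._backward = bwd
        return out

    def segment_sum(self, segment_ids: np.ndarray, n_segments: int) -> "Tensor":
        """Sum rows (or entries) sharing a segment id; backward gathers."""
        segment_ids = np.asarray(segment_ids, dtype=np.intp)
        shape = (n_segments,) + self.data.shape[1:]
        acc = np.zeros(shape, dtype=np.float64)
        np.add.at(acc, segment_ids, self.data)
        out = Tensor(acc, parents=(self,))
        out._backward = lambda g: self._accumulate(g[segment_ids])
        return out


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam with optional coupled L2 weight decay (decay added to gradients)."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
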