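"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the graph-attention encoder and gMLP decoders in
this package: broadcast-aware arithmetic, matmul, elementwise nonlinearities,
reductions, row gather / segment-sum (the two primitives message passing
needs), concatenation and reshaping.  Gradients are accumulated by a
topological sweep over the recorded tape.

The engine is deliberately small and CPU-only; float64 throughout.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "Parameter",
    "IndexMap",
    "concat",
    "gather_rows",
    "segment_sum",
    "stack",
    "Adam",
]


class IndexMap:
    """Row gather/scatter between an (n,) node axis and an (E,) edge axis.

    Wraps a pair of sparse 0/1 matrices so that both the forward op and
    its adjoint are single CSR products (much faster on one CPU than
    fancy indexing plus ``np.add.at``).
    """

    def __init__(self, idx: np.ndarray, n: int):
        self.idx = np.asarray(idx, dtype=np.intp)
        self.n = int(n)
        e = len(self.idx)
        ones = np.ones(e)
        self._gather = sp.csr_matrix(
            (ones, (np.arange(e), self.idx)), shape=(e, self.n)
        )
        self._scatter = self._gather.T.tocsr()

    def gather(self, arr: np.ndarray) -> np.ndarray:
        return self._gather @ arr

    def scatter_add(self, arr: np.ndarray) -> np.ndarray:
        return self._scatter @ arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- helpers ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        # max(x, slope*x) == leaky relu for 0 < slope < 1; avoids np.where
        out_data = np.maximum(self.data, slope * self.data)

        def backward(g):
            if self.requires_grad:
                factor = slope + (1.0 - slope) * (self.data > 0)
                self._accum(g * factor)

        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.maximum(self.data, 0.0) + expm1

        def backward(g):
            if self.requires_grad:
                self._accum(g * (pos + (~pos) * (expm1 + alpha)))

        return self._make(out_data, (self,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi)
        inner = c * (self.data + 0.044715 * self.data**3)
        t = np.tanh(inner)
        out_data = 0.5 * self.data * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * self.data**2)
                grad = 0.5 * (1.0 + t) + 0.5 * self.data * (1.0 - t**2) * dinner
                self._accum(g * grad)

        return self._make(out_data, (self,), backward)

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, key, g)
                self._accum(acc)

        return self._make(self.data[key], (self,), backward)

    # -- autograd ----------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    return concat([t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors], axis=axis)


def gather_rows(x: Tensor, idx: np.ndarray | IndexMap) -> Tensor:
    """Select rows ``x[idx]`` along axis 0 (gradient scatter-adds back)."""
    imap = idx if isinstance(idx, IndexMap) else IndexMap(idx, x.shape[0])

    def backward(g):
        if x.requires_grad:
            x._accum(imap.scatter_add(g))

    out = Tensor(imap.gather(x.data))
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def segment_sum(x: Tensor, segments: np.ndarray | IndexMap, num_segments: int | None = None) -> Tensor:
    """Sum rows of `x` into segment buckets given per-row segment ids."""
    imap = (
        segments
        if isinstance(segments, IndexMap)
        else IndexMap(segments, num_segments)
    )

    def backward(g):
        if x.requires_grad:
            x._accum(imap.gather(g))

    out = Tensor(imap.scatter_add(x.data))
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


class Adam:
    """Adaptive-moment optimizer over a list of Parameters."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
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
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
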