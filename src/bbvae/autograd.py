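"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The network stack in this package is small (a few dozen distinct array
operations per forward pass), so instead of pulling in a deep-learning
framework we keep a compact tape-based autodiff core: a :class:`Tensor`
wraps an ``ndarray`` and records, for every produced value, a closure that
maps the output gradient back onto the operands.  Gradients follow NumPy
broadcasting semantics; broadcast axes are summed out on the way back.

Only the operations the model actually uses are implemented.  Everything
runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "cross", "segment_sum", "gather"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the tape information needed for backpropagation."""

    __slots__ = ("value", "parents", "_backward", "requires_grad", "grad")

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None
        self.grad = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.value + other.value, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.value, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.value, self.shape))
            other._accumulate(_unbroadcast(g * self.value, other.shape))

        return Tensor(self.value * other.value, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.value, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.value / other.value**2, other.shape)
            )

        return Tensor(self.value / other.value, parents=(self, other), backward=bwd)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g):
            self._accumulate(g * exponent * self.value ** (exponent - 1))

        return Tensor(self.value**exponent, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g):
            a, b = self.value, other.value
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul operands must be >= 2-D")
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(np.matmul(self.value, other.value), parents=(self, other), backward=bwd)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_val = np.exp(self.value)

        def bwd(g):
            self._accumulate(g * out_val)

        return Tensor(out_val, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.value)

        return Tensor(np.log(self.value), parents=(self,), backward=bwd)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def bwd(g):
            self._accumulate(g * 0.5 / out_val)

        return Tensor(out_val, parents=(self,), backward=bwd)

    def relu(self):
        mask = self.value > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.value * mask, parents=(self,), backward=bwd)

    def sigmoid(self):
        from scipy.special import expit

        out_val = expit(self.value)

        def bwd(g):
            self._accumulate(g * out_val * (1.0 - out_val))

        return Tensor(out_val, parents=(self,), backward=bwd)

    def tanh(self):
        out_val = np.tanh(self.value)

        def bwd(g):
            self._accumulate(g * (1.0 - out_val**2))

        return Tensor(out_val, parents=(self,), backward=bwd)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def softmax(self, axis=-1):
        shifted = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_val = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out_val).sum(axis=axis, keepdims=True)
            self._accumulate(out_val * (g - dot))

        return Tensor(out_val, parents=(self,), backward=bwd)

    # ----------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.value.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inverse))

        return Tensor(self.value.transpose(axes), parents=(self,), backward=bwd)

    def swapaxes(self, a, b):
        def bwd(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.value, a, b), parents=(self,), backward=bwd)

    def __getitem__(self, key):
        # basic indexing (ints/slices) maps each output element to a distinct
        # input element, so the backward pass is a plain assignment; fancy
        # indexing may repeat elements and needs scatter-add
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple) and all(isinstance(k, (int, slice)) for k in key)
        )

        def bwd(g):
            full = np.zeros(self.shape)
            if basic:
                full[key] = g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor(self.value[key], parents=(self,), backward=bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bwd,
    )


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Cross product along the last axis (size 3)."""
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        # d/da (a x b) applied to g is g x b... more precisely grad_a = b x g
        a._accumulate(_unbroadcast(np.cross(b.value, g), a.shape))
        b._accumulate(_unbroadcast(np.cross(g, a.value), b.shape))

    return Tensor(np.cross(a.value, b.value), parents=(a, b), backward=bwd)


def gather(x: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``x[indices]`` along axis 0 with scatter-add backward."""
    x = as_tensor(x)
    indices = np.asarray(indices)

    def bwd(g):
        full = np.zeros(x.shape)
        np.add.at(full, indices, g)
        x._accumulate(full)

    return Tensor(x.value[indices], parents=(x,), backward=bwd)


class SparseOp:
    """A fixed sparse selection/aggregation matrix usable inside the tape.

    Wraps a scipy CSR matrix S (and its precomputed transpose) so that
    ``S @ x`` has the backward pass ``S.T @ g``.  Row-gather and
    segment-sum over graph edges are both instances of this.
    """

    def __init__(self, S):
        self.S = S.tocsr()
        self.ST = self.S.T.tocsr()

    @classmethod
    def gather(cls, indices: np.ndarray, n_rows: int) -> "SparseOp":
        from scipy import sparse

        E = len(indices)
        return cls(sparse.csr_matrix(
            (np.ones(E), (np.arange(E), indices)), shape=(E, n_rows)
        ))

    @classmethod
    def scatter(cls, indices: np.ndarray, n_rows: int) -> "SparseOp":
        from scipy import sparse

        E = len(indices)
        return cls(sparse.csr_matrix(
            (np.ones(E), (indices, np.arange(E))), shape=(n_rows, E)
        ))

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)

        def bwd(g):
            x._accumulate(self.ST @ g)

        return Tensor(self.S @ x.value, parents=(x,), backward=bwd)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids)
    out_val = np.zeros((num_segments,) + x.shape[1:])
    np.add.at(out_val, segment_ids, x.value)

    def bwd(g):
        x._accumulate(g[segment_ids])

    return Tensor(out_val, parents=(x,), backward=bwd)
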