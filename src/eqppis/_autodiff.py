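"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based scalar/tensor autodiff engine supporting exactly the operations
the equivariant network needs: dense linear algebra, smooth elementwise
nonlinearities, row gather/scatter (for pooling and unpooling) and segment
sums (for neighbour message aggregation). Everything runs in float64.

Gradients are accumulated by reverse topological traversal; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "segment_sum", "scatter_rows", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached backward closure."""

    __slots__ = (
        "data", "grad", "requires_grad", "_backward", "_prev", "name", "_grad_owned"
    )

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev = tuple(_prev)
        self.name = name
        self._grad_owned = False

    # -- basic introspection ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        # first contribution is adopted by reference (no allocation); a second
        # contribution triggers a copy-on-write so shared arrays stay intact
        if self.grad is None:
            if g.shape != self.data.shape:
                g = np.broadcast_to(g, self.data.shape)
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = backward
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = backward
        return out

    # -- reductions and elementwise maps ------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = expit(self.data)
        out = Tensor(s, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = backward
        return out

    def silu(self) -> "Tensor":
        """x * sigmoid(x) — the smooth nonlinearity used inside the MLPs."""
        s = expit(self.data)
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (s + self.data * s * (1.0 - s)))

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = Tensor(r, self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / r)

        out._backward = backward
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """max(self, lo) with gradient passed only where self > lo."""
        out = Tensor(np.maximum(self.data, lo), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > lo))

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows (axis 0) at integer indices `idx`."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward():
            if self.requires_grad:
                self._accum(_rows_sum(idx, out.grad, self.data.shape[0]))

        out._backward = backward
        return out

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        self._grad_owned = True
        for node in reversed(topo):
            if node.requires_grad and node._backward is not None and node.grad is not None:
                node._backward()


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`."""
    ts = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in ts], axis=axis),
        any(t.requires_grad for t in ts),
        ts,
    )
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = backward
    return out


def _rows_sum(ids: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Sum `values` rows into `n` buckets by id (sorted reduceat, which is
    much faster than np.add.at for the edge counts seen here)."""
    out = np.zeros((n,) + values.shape[1:], dtype=np.float64)
    if ids.size == 0:
        return out
    if ids.size and np.all(ids[:-1] <= ids[1:]):
        sids, svals = ids, values
    else:
        order = np.argsort(ids, kind="stable")
        sids, svals = ids[order], values[order]
    uniq, starts = np.unique(sids, return_index=True)
    out[uniq] = np.add.reduceat(svals, starts, axis=0)
    return out


def segment_sum(t: Tensor, seg_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `t` into `n_segments` buckets given per-row segment ids."""
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out = Tensor(_rows_sum(seg_ids, t.data, n_segments), t.requires_grad, (t,))

    def backward():
        if t.requires_grad:
            t._accum(out.grad[seg_ids])

    out._backward = backward
    return out


def scatter_rows(t: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Place row j of `t` at row idx[j] of a zero matrix with `n_rows` rows.

    Indices must be unique (each output row receives at most one input row).
    """
    idx = np.asarray(idx, dtype=np.intp)
    if len(np.unique(idx)) != len(idx):
        raise ValueError("scatter_rows requires unique indices")
    if idx.size and (idx.min() < 0 or idx.max() >= n_rows):
        raise IndexError("scatter index out of range")
    return segment_sum(t, idx, n_rows)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; ties route the gradient to the first argument."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask = a.data >= b.data
    out = Tensor(np.where(mask, a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def backward():
        if a.requires_grad:
            a._accum(out.grad * mask)
        if b.requires_grad:
            b._accum(out.grad * ~mask)

    out._backward = backward
    return out
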