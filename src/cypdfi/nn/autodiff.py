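"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a numpy
array, operations build a DAG, and :meth:`Tensor.backward` accumulates
gradients by reverse topological traversal.  Only the operations the DFI
model needs are implemented (broadcast-aware elementwise arithmetic, matmul,
gather/segment reductions for graphs, masked softmax for attention, and the
activation functions of the architecture).  Gradient correctness is checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "segment_sum",
    "masked_softmax",
    "additive_scores",
    "set_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in prev if isinstance(p, Tensor))
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._prev = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._prev:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
        # leaves with requires_grad inside the graph (handled above); done.

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return ((self, _unbroadcast(g, self.shape)), (other, _unbroadcast(g, other.shape)))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            return ((self, -g),)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return ((self, g * exponent * self.data ** (exponent - 1.0)),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return ((a, ga), (b, gb))

        return Tensor._make(out_data, (self, other), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return ((self, full),)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions and shape ops ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            return ((self, g.reshape(orig)),)

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            return ((self, g.transpose(inv)),)

        return Tensor._make(out_data, (self,), backward)

    # -- nonlinearities ---------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - out_data**2)),)

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
            np.exp(np.clip(self.data, -500, 500)) / (1.0 + np.exp(np.clip(self.data, -500, 500))),
        )

        def backward(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return ((self, g * out_data),)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return ((self, g / self.data),)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            return ((self, g * (self.data > 0)),)

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        out_data = np.where(self.data > 0, self.data, slope * self.data)

        def backward(g):
            return ((self, g * np.where(self.data > 0, 1.0, slope)),)

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def backward(g):
            pdf = np.exp(-0.5 * x**2) / math.sqrt(2.0 * math.pi)
            return ((self, g * (cdf + x * pdf)),)

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)

        def backward(g):
            inside = (self.data > lo) & (self.data < hi)
            return ((self, g * inside),)

        return Tensor._make(out_data, (self,), backward)


# -- free functions -------------------------------------------------------------


def _scatter_add_rows(shape: tuple[int, ...], idx: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Rows of ``g`` summed into a zero array of ``shape`` at row indices
    ``idx`` (duplicates accumulate).  Sort + reduceat; much faster than
    ``np.add.at`` for large index sets."""
    out = np.zeros(shape, dtype=np.float64)
    if idx.size == 0:
        return out
    order = np.argsort(idx, kind="stable")
    sid = idx[order]
    gs = g[order]
    starts = np.flatnonzero(np.r_[True, sid[1:] != sid[:-1]])
    out[sid[starts]] = np.add.reduceat(gs, starts, axis=0)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            grads.append((t, g[tuple(idx)]))
        return grads

    return Tensor._make(out_data, tensors, backward)


def gather(x: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows along axis 0; gradient scatter-adds back."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = x.data[indices]

    def backward(g):
        return ((x, _scatter_add_rows(x.shape, indices, g)),)

    return Tensor._make(out_data, (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets; gradient gathers."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = _scatter_add_rows((num_segments,) + x.shape[1:], segment_ids, x.data)

    def backward(g):
        return ((x, g[segment_ids]),)

    return Tensor._make(out_data, (x,), backward)


def additive_scores(qp: Tensor, kp: Tensor, v: Tensor) -> Tensor:
    """Fused additive-attention score: ``e[b,i,j,k] = v[i] . tanh(qp[i,j] + kp[b,i,k])``.

    qp: (heads, Q, dh); kp: (B, heads, L, dh); v: (heads, dh) ->
    out: (B, heads, Q, L).  One primitive instead of a chain of broadcast
    ops, since this five-dimensional intermediate dominates the attention
    block's cost.
    """
    t = np.tanh(qp.data[None, :, :, None, :] + kp.data[:, :, None, :, :])  # (B,heads,Q,L,dh)
    out_data = np.einsum("bijkd,id->bijk", t, v.data, optimize=True)

    def backward(g):
        gt = g[..., None] * v.data[None, :, None, None, :] * (1.0 - t**2)
        gqp = gt.sum(axis=(0, 3))
        gkp = gt.sum(axis=2)
        gv = np.einsum("bijkd,bijk->id", t, g, optimize=True)
        return ((qp, gqp), (kp, gkp), (v, gv))

    return Tensor._make(out_data, (qp, kp, v), backward)


def set_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mask: np.ndarray | None = None,
    eps: float = 1e-5,
) -> Tensor:
    """Fused set normalization: standardize jointly over the last two axes
    (set elements x features), then apply a per-feature affine.

    ``mask`` (..., L) excludes padded elements from the statistics; masked
    positions emit exact zeros and receive zero gradient.
    """
    data = x.data
    if mask is None:
        m = np.ones(data.shape[:-1], dtype=bool)
    else:
        m = np.broadcast_to(np.asarray(mask, dtype=bool), data.shape[:-1])
    counts = m.sum(axis=-1, keepdims=True)[..., None] * data.shape[-1]  # (..., 1, 1)
    if np.any(counts == 0):
        raise ValueError("set normalization over an empty set")
    mf = m[..., None].astype(np.float64)
    mean = (data * mf).sum(axis=(-1, -2), keepdims=True) / counts
    centered = (data - mean) * mf
    var = (centered**2).sum(axis=(-1, -2), keepdims=True) / counts
    inv_sigma = 1.0 / np.sqrt(var + eps)
    z = centered * inv_sigma
    out_data = (z * gamma.data + beta.data) * mf

    def backward(g):
        g = g * mf
        gz = g * gamma.data
        s1 = gz.sum(axis=(-1, -2), keepdims=True) / counts
        s2 = (gz * z).sum(axis=(-1, -2), keepdims=True) / counts
        gx = inv_sigma * (gz - s1 - z * s2) * mf
        axes = tuple(range(g.ndim - 1))
        ggamma = (g * z).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        return ((x, gx), (gamma, ggamma), (beta, gbeta))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def masked_softmax(x: Tensor, mask: np.ndarray | None = None, axis: int = -1) -> Tensor:
    """Softmax along ``axis``; positions where ``mask`` is False get weight 0.

    Raises if any softmax row has no unmasked position.
    """
    data = x.data
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), data.shape)
        if not np.all(mask.any(axis=axis)):
            raise ValueError("softmax row with all keys masked")
        data = np.where(mask, data, -np.inf)
    shifted = data - data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((x, out_data * (g - dot)),)

    return Tensor._make(out_data, (x,), backward)
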