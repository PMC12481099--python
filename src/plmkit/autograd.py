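"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are small enough to run on a CPU in pure numpy;
this module provides the gradient machinery needed to train them (masked-LM
pretraining, LoRA and head fine-tuning, positional-embedding retraining).
Only the operations the transformer stack actually uses are implemented:
broadcast arithmetic, matmul, a few elementwise nonlinearities, reductions,
indexing/gather, concatenation, and segment-wise softmax/mean used by
packed-batch pooling.

Gradients accumulate in the dtype of the forward value (float32 by default),
and every op handles numpy broadcasting by summing gradients over the
broadcast axes.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "as_tensor", "concat", "stack", "take_rows", "segment_softmax", "segment_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting added or expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], Iterable[np.ndarray | None]]) -> "Tensor":
        out = cls(data)
        live = [p for p in parents if isinstance(p, Tensor) and p.requires_grad]
        if live:
            out.requires_grad = True
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))

            def _bw():
                grads = backward(out.grad)
                for p, g in zip(parents, grads):
                    if g is None or not isinstance(p, Tensor) or not p.requires_grad:
                        continue
                    g = np.asarray(g, dtype=p.data.dtype)
                    if p.grad is None:
                        p.grad = np.zeros_like(p.data)
                    p.grad += g

            out._backward = _bw
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backprop -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python scalars stay "weak" so float32 graphs do not upcast
            return Tensor._from_op(self.data + other, (self,), lambda g: (g,))
        other = as_tensor(other)
        return Tensor._from_op(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor._from_op(self.data * other, (self,), lambda g: (g * other,))
        other = as_tensor(other)
        return Tensor._from_op(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.data.shape),
                       _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        return Tensor._from_op(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.data.shape),
                       _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor._from_op(
            self.data ** exponent, (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def _bw(g):
            if b.ndim == 1:
                ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                gb = a.T @ g if a.ndim > 1 else a * g
            elif a.ndim == 1:
                ga = g @ b.T if b.ndim == 2 else None
                gb = np.multiply.outer(a, g)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._from_op(a @ b, (self, other), _bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(np.where(mask, self.data, 0.0).astype(self.data.dtype),
                               (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data.astype(self.data.dtype), (self,),
                               lambda g: (g * out_data * (1.0 - out_data),))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return Tensor._from_op((x * cdf).astype(x.dtype), (self,),
                               lambda g: (g * (cdf + x * pdf),))

    def silu(self):
        x = self.data
        sig = 1.0 / (1.0 + np.exp(-x))
        return Tensor._from_op((x * sig).astype(x.dtype), (self,),
                               lambda g: (g * (sig * (1.0 + x * (1.0 - sig))),))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def _bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape),)

        return Tensor._from_op(out_data, (self,), _bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._from_op(self.data.reshape(shape), (self,),
                               lambda g: (g.reshape(self.data.shape),))

    def swapaxes(self, a: int, b: int):
        return Tensor._from_op(np.swapaxes(self.data, a, b), (self,),
                               lambda g: (np.swapaxes(g, a, b),))

    @property
    def T(self):
        return Tensor._from_op(self.data.T, (self,), lambda g: (g.T,))

    def __getitem__(self, key):
        def _bw(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._from_op(self.data[key], (self,), _bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tensors, _bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def _bw(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._from_op(np.stack([t.data for t in tensors], axis=axis), tensors, _bw)


def take_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: gather rows of a 2-D table; backward scatter-adds."""
    indices = np.asarray(indices)

    def _bw(g):
        out = np.zeros_like(table.data)
        np.add.at(out, indices, g)
        return (out,)

    return Tensor._from_op(table.data[indices], (table,), _bw)


def _segment_reduceat(values: np.ndarray, boundaries: np.ndarray, op) -> np.ndarray:
    return op.reduceat(values, boundaries[:-1], axis=0)


def segment_softmax(scores: Tensor, boundaries: np.ndarray) -> Tensor:
    """Softmax over axis 0 computed independently within each segment.

    `boundaries` are cumulative segment offsets (len = n_segments + 1), as in a
    packed batch; rows of `scores` belonging to one segment are normalized
    together, so attention-pooling weights never cross sequence boundaries.
    """
    scores_np = scores.data if isinstance(scores, Tensor) else np.asarray(scores)
    boundaries = np.asarray(boundaries)
    lengths = np.diff(boundaries)
    if np.any(lengths <= 0):
        raise ValueError("segments must be non-empty")
    seg_of = np.repeat(np.arange(len(lengths)), lengths)
    seg_max = _segment_reduceat(scores_np, boundaries, np.maximum)
    shifted = scores_np - seg_max[seg_of]
    e = np.exp(shifted)
    denom = _segment_reduceat(e, boundaries, np.add)
    probs = e / denom[seg_of]

    def _bw(g):
        dot = _segment_reduceat(probs * g, boundaries, np.add)
        return (probs * (g - dot[seg_of]),)

    return Tensor._from_op(probs.astype(scores_np.dtype), (scores,) if isinstance(scores, Tensor) else (), _bw)


def segment_mean(values: Tensor, boundaries: np.ndarray) -> Tensor:
    """Per-segment mean over axis 0 (used for packed mean-pooling)."""
    values_np = values.data if isinstance(values, Tensor) else np.asarray(values)
    boundaries = np.asarray(boundaries)
    lengths = np.diff(boundaries)
    if np.any(lengths <= 0):
        raise ValueError("segments must be non-empty")
    sums = _segment_reduceat(values_np, boundaries, np.add)
    out = sums / lengths[:, None].astype(values_np.dtype)

    def _bw(g):
        scaled = g / lengths[:, None].astype(g.dtype)
        return (np.repeat(scaled, lengths, axis=0),)

    return Tensor._from_op(out.astype(values_np.dtype), (values,) if isinstance(values, Tensor) else (), _bw)
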