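"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded graph.  The op set is exactly what the network layers in
:mod:`h2a.nn` need: broadcasting arithmetic, matmul, elementwise
nonlinearities, reductions, reshaping/transposition, concatenation, fancy
row gathering and segment sums (for sparse attention aggregation).

Gradients are accumulated in ``float64``; no tape reuse, no higher-order
derivatives.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                ga = g @ b.T if b.ndim == 2 else g * b
            else:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim >= 2 else np.outer(g, b)
            if b.ndim == 1:
                gb = a.T @ g if a.ndim == 2 else g * a
            else:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim >= 2 else np.outer(a, g)
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,),
                               lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,),
                               lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        deriv = np.where(self.data > 0, 1.0, slope)
        return Tensor._from_op(np.where(self.data > 0, self.data,
                                        slope * self.data),
                               (self,), lambda g: (g * deriv,))

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)
        deriv = np.where(self.data > 0, 1.0, neg + alpha)
        return Tensor._from_op(out_data, (self,), lambda g: (g * deriv,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,),
                               lambda g: (g * out_data * (1.0 - out_data),))

    def softplus(self):
        # numerically stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._from_op(out_data, (self,), lambda g: (g * sig,))

    def clip_min(self, lo: float):
        mask = self.data > lo
        return Tensor._from_op(np.maximum(self.data, lo), (self,),
                               lambda g: (g * mask,))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g_ = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_, self.data.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape
        return Tensor._from_op(out_data, (self,),
                               lambda g: (g.reshape(src_shape),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._from_op(self.data.transpose(axes), (self,),
                               lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def gather(self, index, axis: int = 0):
        """Select rows (or slices along ``axis``) with an integer index array."""
        index = np.asarray(index)
        out_data = np.take(self.data, index, axis=axis)
        src_shape = self.data.shape

        def backward(g):
            acc = np.zeros(src_shape, dtype=np.float64)
            if axis == 0:
                np.add.at(acc, index, g)
            else:
                acc_m = np.moveaxis(acc, axis, 0)
                np.add.at(acc_m, index, np.moveaxis(g, axis, 0))
            return (acc,)

        return Tensor._from_op(out_data, (self,), backward)

    def take_flat(self, index):
        """Gather from the flattened array; used for im2col convolution."""
        index = np.asarray(index)
        flat = self.data.reshape(-1)
        out_data = flat[index]
        src_shape = self.data.shape

        def backward(g):
            acc = np.zeros(flat.shape, dtype=np.float64)
            np.add.at(acc, index.reshape(-1), g.reshape(-1))
            return (acc.reshape(src_shape),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- backward --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def segment_sum(t: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids)
    out_shape = (num_segments,) + t.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out_data, segment_ids, t.data)
    return Tensor._from_op(out_data, (t,), lambda g: (g[segment_ids],))


def pad2d(t: Tensor, p: int) -> Tensor:
    """Zero-pad the last two axes of ``t`` by ``p`` on every side."""
    if p == 0:
        return t
    widths = [(0, 0)] * (t.ndim - 2) + [(p, p), (p, p)]
    out_data = np.pad(t.data, widths)
    sl = (Ellipsis, slice(p, -p), slice(p, -p))
    return Tensor._from_op(out_data, (t,), lambda g: (g[sl],))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Softmax composed from primitive ops (max-shift is constant w.r.t. grad)."""
    shift = Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_softmax(scores: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Softmax of a flat score vector within segments (e.g. edge scores per
    destination node)."""
    segment_ids = np.asarray(segment_ids)
    # per-segment max for stability; constant shift, no gradient needed
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    e = (scores - Tensor(seg_max[segment_ids])).exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom.gather(segment_ids)
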