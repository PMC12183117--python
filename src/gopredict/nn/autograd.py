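"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is a small tape-based engine sized for the package's models: dense
layers, SiLU/sigmoid nonlinearities, gather/segment primitives for
message passing on edge lists, and numerically stable reductions
(log-sum-exp, BCE-with-logits).  Arrays are float64 throughout; gradients
accumulate into ``Tensor.grad`` on :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape*, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- operators -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(
        data,
        requires_grad=requires,
        parents=[p for p in parents if p.requires_grad],
        backward=backward if requires else None,
    )


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad)
        if b.requires_grad:
            b._accumulate(grad)

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad * b.data)
        if b.requires_grad:
            b._accumulate(grad * a.data)

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad / b.data)
        if b.requires_grad:
            b._accumulate(-grad * a.data / (b.data**2))

    return _node(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(grad):
        if a.requires_grad:
            a._accumulate(grad @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ grad)

    return _node(out_data, (a, b), backward)


def transpose(a: Tensor) -> Tensor:
    def backward(grad):
        a._accumulate(grad.T)

    return _node(a.data.T, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = _stable_sigmoid(a.data)

    def backward(grad):
        a._accumulate(grad * s * (1.0 - s))

    return _node(s, (a,), backward)


def silu(a) -> Tensor:
    """x * sigmoid(x) (the SiLU / swish activation)."""
    a = _wrap(a)
    s = _stable_sigmoid(a.data)
    out_data = a.data * s

    def backward(grad):
        a._accumulate(grad * (s + a.data * s * (1.0 - s)))

    return _node(out_data, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, negative_slope * a.data)

    def backward(grad):
        a._accumulate(grad * np.where(mask, 1.0, negative_slope))

    return _node(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(grad):
        a._accumulate(grad * out_data)

    return _node(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)

    def backward(grad):
        a._accumulate(grad / a.data)

    return _node(np.log(a.data), (a,), backward)


def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(grad):
        g = np.asarray(grad)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _node(out_data, (a,), backward)


def mean(a, axis=None) -> Tensor:
    a = _wrap(a)
    count = a.data.size if axis is None else a.data.shape[axis]
    return mul(tensor_sum(a, axis=axis), 1.0 / count)


def logsumexp(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log(sum(exp(a), axis)); gradient is softmax(a)."""
    a = _wrap(a)
    m = a.data.max(axis=axis, keepdims=True)
    shifted = np.exp(a.data - m)
    total = shifted.sum(axis=axis, keepdims=True)
    out_data = np.squeeze(m + np.log(total), axis=axis)
    soft = shifted / total

    def backward(grad):
        a._accumulate(np.expand_dims(np.asarray(grad), axis) * soft)

    return _node(out_data, (a,), backward)


def normalize_rows(a: Tensor, eps: float = 1e-12) -> Tensor:
    """L2-normalize each row; all-zero rows stay zero (their gradient is 0,
    matching the convention that cosine similarity with a zero vector is 0)."""
    a = _wrap(a)
    norms = np.linalg.norm(a.data, axis=1, keepdims=True)
    safe = np.where(norms > eps, norms, 1.0)
    zero_rows = (norms <= eps).ravel()
    out_data = a.data / safe
    out_data[zero_rows] = 0.0

    def backward(grad):
        g = np.asarray(grad, dtype=np.float64)
        dot = (g * out_data).sum(axis=1, keepdims=True)
        ga = (g - out_data * dot) / safe
        ga[zero_rows] = 0.0
        a._accumulate(ga)

    return _node(out_data, (a,), backward)


def take_diag(a: Tensor) -> Tensor:
    """Diagonal of a square matrix as a vector."""
    a = _wrap(a)
    n = a.data.shape[0]

    def backward(grad):
        ga = np.zeros_like(a.data)
        ga[np.arange(n), np.arange(n)] = grad
        a._accumulate(ga)

    return _node(np.diagonal(a.data).copy(), (a,), backward)


def gather_rows(a: Tensor, index: np.ndarray) -> Tensor:
    """Row lookup out[i] = a[index[i]]; gradient scatter-adds back."""
    a = _wrap(a)
    index = np.asarray(index, dtype=np.int64)

    def backward(grad):
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, grad)
        a._accumulate(ga)

    return _node(a.data[index], (a,), backward)


def segment_sum(a: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = sum of rows of *a* whose segment id is s."""
    a = _wrap(a)
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_shape = (num_segments,) + a.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out_data, segment_ids, a.data)

    def backward(grad):
        a._accumulate(np.asarray(grad)[segment_ids])

    return _node(out_data, (a,), backward)


def concat_columns(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    tensors = [_wrap(t) for t in tensors]
    widths = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    offsets = np.cumsum([0] + widths)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(grad[:, lo:hi])

    return _node(out_data, tuple(tensors), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not train or rate <= 0.0:
        return _wrap(a)
    a = _wrap(a)
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits, numerically stable:
    softplus(z) - y*z averaged over all entries."""
    logits = _wrap(logits)
    y = np.asarray(targets, dtype=np.float64)
    if y.shape != logits.data.shape:
        raise ValueError(
            f"targets shape {y.shape} != logits shape {logits.data.shape}"
        )
    z = logits.data
    # log(1 + e^z) = max(z, 0) + log1p(e^{-|z|})
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    out_data = np.mean(softplus - y * z)
    size = z.size

    def backward(grad):
        logits._accumulate(grad * (_stable_sigmoid(z) - y) / size)

    return _node(out_data, (logits,), backward)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
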