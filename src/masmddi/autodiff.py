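"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (molecular graphs of tens of atoms,
hidden widths of order 100), so the network is expressed directly on
NumPy with a tape of :class:`Tensor` nodes rather than through a deep
learning framework.  The op set is exactly what the forward pass of the
encoder, attention and scoring modules needs: broadcast add/mul, matmul
(with leading batch dimensions), a fused affine map, elementwise
nonlinearities, reductions, concat/stack and an index-gather.

Gradients are accumulated into ``Tensor.grad`` by :func:`backward`,
which topologically sorts the tape rooted at the loss.  Correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "linear",
    "relu",
    "sigmoid",
    "tanh",
    "log",
    "clip",
    "reduce_sum",
    "reduce_mean",
    "concat",
    "stack",
    "reshape",
    "transpose",
    "gather",
    "backward",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape construction (evaluation-only forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A node in the computation tape.

    ``value`` is an ndarray; ``grad`` is filled by :func:`backward`.
    Leaf tensors created with ``requires_grad=True`` are the trainable
    parameters.
    """

    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        bwd: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, leaf={self.bwd is None})"


def constant(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64))


def parameter(value) -> Tensor:
    return Tensor(np.asarray(value, dtype=np.float64), requires_grad=True)


def _node(value, parents, bwd) -> Tensor:
    if not _GRAD_ENABLED:
        return Tensor(value)
    return Tensor(value, parents=tuple(parents), bwd=bwd)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.value + b.value
    return _node(out, (a, b), lambda g: (_unbroadcast(g, a.value.shape),
                                         _unbroadcast(g, b.value.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.value * b.value
    return _node(out, (a, b), lambda g: (_unbroadcast(g * b.value, a.value.shape),
                                         _unbroadcast(g * a.value, b.value.shape)))


def _swap_last(x: np.ndarray) -> np.ndarray:
    return np.swapaxes(x, -1, -2)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b`` with NumPy batch semantics on leading dimensions."""
    out = a.value @ b.value

    def bwd(g):
        ga = g @ _swap_last(b.value) if a.value.ndim > 1 else _swap_last(b.value) @ g
        gb = _swap_last(a.value) @ g
        return _unbroadcast(ga, a.value.shape), _unbroadcast(gb, b.value.shape)

    return _node(out, (a, b), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map ``x @ w + b`` for ``x`` of shape (..., d_in).

    Fused so that the weight gradient is a single flattened matmul
    regardless of how many batch dimensions ``x`` carries.
    """
    out = x.value @ w.value
    if b is not None:
        out = out + b.value
    d_in, d_out = w.value.shape

    def bwd(g):
        g2 = g.reshape(-1, d_out)
        x2 = x.value.reshape(-1, d_in)
        gx = (g2 @ w.value.T).reshape(x.value.shape)
        gw = x2.T @ g2
        if b is None:
            return gx, gw
        return gx, gw, g2.sum(axis=0)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, bwd)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.value, 0.0)
    return _node(out, (x,), lambda g: (g * (x.value > 0.0),))


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.value))
    return _node(out, (x,), lambda g: (g * out * (1.0 - out),))


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.value)
    return _node(out, (x,), lambda g: (g * (1.0 - out * out),))


def log(x: Tensor) -> Tensor:
    out = np.log(x.value)
    return _node(out, (x,), lambda g: (g / x.value,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient is zero outside [lo, hi]."""
    out = np.clip(x.value, lo, hi)
    inside = (x.value >= lo) & (x.value <= hi)
    return _node(out, (x,), lambda g: (g * inside,))


def reduce_sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.value.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.value.shape).copy(),)

    return _node(out, (x,), bwd)


def reduce_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.value.mean(axis=axis, keepdims=keepdims)
    denom = x.value.size if axis is None else np.prod(
        [x.value.shape[a] for a in np.atleast_1d(axis)])

    def bwd(g):
        g = np.asarray(g) / denom
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.value.shape).copy(),)

    return _node(out, (x,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = np.concatenate([t.value for t in tensors], axis=axis)
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = np.stack([t.value for t in tensors], axis=axis)

    def bwd(g):
        return tuple(np.moveaxis(g, axis, 0))

    return _node(out, tuple(tensors), bwd)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = x.value.reshape(shape)
    return _node(out, (x,), lambda g: (g.reshape(x.value.shape),))


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    out = x.value.transpose(axes)
    inv = np.argsort(axes)
    return _node(out, (x,), lambda g: (g.transpose(inv),))


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` along axis 0; backward scatter-adds."""
    idx = np.asarray(idx, dtype=np.intp)
    out = x.value[idx]

    def bwd(g):
        gx = np.zeros_like(x.value)
        np.add.at(gx, idx, g)
        return (gx,)

    return _node(out, (x,), bwd)


def backward(loss: Tensor) -> None:
    """Accumulate d(loss)/d(leaf) into ``grad`` of every reachable tensor."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack_: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack_.append((p, False))

    loss.grad = np.ones_like(loss.value)
    for node in reversed(order):
        if node.bwd is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node.bwd(node.grad)):
            g = np.asarray(g, dtype=np.float64)
            if parent.grad is None:
                parent.grad = g.copy()
            else:
                parent.grad = parent.grad + g
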