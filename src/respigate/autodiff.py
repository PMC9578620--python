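"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The sequence predictors in :mod:`respigate.models` are small enough that a
compact tape-based engine is sufficient: each operation records its
parents and a closure that maps the output gradient to parent gradients,
and :meth:`Tensor.backward` walks the tape in reverse topological order.
Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.

Recurrent layers get a fused primitive (:func:`lstm_layer`) whose backward
is hand-written backpropagation-through-time — building the unrolled graph
node by node would dominate the runtime for deep narrow stacks.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

from .errors import ShapeError

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = backward

    # -- construction -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ShapeError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth explodes on long tapes
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other, self.data.dtype))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, _as_tensor(other, self.data.dtype) * -1.0)

    def __rsub__(self, other):
        return add(_as_tensor(other, self.data.dtype), self * -1.0)

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self.data.dtype))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, _as_tensor(1.0 / other, self.data.dtype))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other, self.data.dtype))

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def swapaxes(self, a: int, b: int):
        return swapaxes(self, a, b)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis, keepdims)


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    # keep the tensor operand's dtype when mixing with python scalars
    if dtype is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=dtype))
    return Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


def parameter(data, rng: np.random.Generator | None = None,
              scale: float | None = None, dtype=np.float64) -> Tensor:
    """A trainable tensor; with ``rng`` given, uniform fan-in initialization
    U(-s, s) with ``s = 1/sqrt(fan_in)`` (last axis) unless overridden."""
    if rng is not None:
        shape = tuple(data) if isinstance(data, (tuple, list)) else data.shape
        if scale is None:
            fan_in = shape[-2] if len(shape) >= 2 else max(shape[-1], 1)
            scale = 1.0 / np.sqrt(fan_in)
        data = rng.uniform(-scale, scale, size=shape)
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


# -- primitive operations -------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return _make(out, (a, b), lambda g: (
        _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return _make(out, (a, b), lambda g: (
        _unbroadcast(g * b.data, a.data.shape),
        _unbroadcast(g * a.data, b.data.shape)))


def power(a: Tensor, p: float) -> Tensor:
    out = a.data**p
    return _make(out, (a,), lambda g: (g * p * a.data ** (p - 1),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(out, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map over the last axis, ``y = x @ w + b``, computed as one
    flattened GEMM (leading axes are folded into the row dimension)."""
    D, F = w.data.shape
    lead = x.data.shape[:-1]
    x2 = x.data.reshape(-1, D)
    y2 = x2 @ w.data
    if b is not None:
        y2 = y2 + b.data
    out = y2.reshape(*lead, F)

    def backward(g):
        g2 = g.reshape(-1, F)
        dx = (g2 @ w.data.T).reshape(x.data.shape)
        dw = x2.T @ g2
        if b is None:
            return dx, dw
        return dx, dw, g2.sum(axis=0)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)
    return _make(out, (a,), lambda g: (g * (1.0 - out * out),))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0.0)
    return _make(out, (a,), lambda g: (g * (a.data > 0),))


def tensor_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape),)

    return _make(out, (a,), backward)


def tensor_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return tensor_sum(a, axis, keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out = a.data.reshape(shape)
    return _make(out, (a,), lambda g: (g.reshape(a.data.shape),))


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    out = np.swapaxes(a.data, ax1, ax2)
    return _make(out, (a,), lambda g: (np.swapaxes(g, ax1, ax2),))


def take(a: Tensor, idx) -> Tensor:
    out = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _make(out, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _make(out, (a,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        axes = tuple(range(g.ndim - 1))
        dgamma = (g * xhat).sum(axis=axes).reshape(gamma.data.shape)
        dbeta = g.sum(axis=axes).reshape(beta.data.shape)
        dxhat = g * gamma.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        return dx, dgamma, dbeta

    return _make(out, (x, gamma, beta), backward)


def lstm_layer(
    x: Tensor,
    wx: Tensor,
    wh: Tensor,
    b: Tensor,
    tied_input_candidate: bool = False,
) -> Tensor:
    """One recurrent layer scanned over time, fused with a hand-written
    backward pass (backpropagation through time).

    ``x`` is (batch, T, input); ``wx`` is (input, 4H); ``wh`` is (H, 4H);
    ``b`` is (4H,) with gate layout ``[i, f, g, o]``.  Initial hidden and
    cell states are zero.  With ``tied_input_candidate`` the input gate
    and the candidate share the candidate preactivation (the literal
    tied-parameter reading of the cell equations): ``i = sigma(a_g)``.

    Returns the hidden-state sequence, shape (batch, T, H).
    """
    from ._lstm_kernels import lstm_scan_backward, lstm_scan_forward

    B, T, I = x.data.shape
    H = wh.data.shape[0]
    if wx.data.shape[1] != 4 * H or b.data.shape[0] != 4 * H:
        raise ShapeError("LSTM parameter shapes inconsistent")
    x2 = np.ascontiguousarray(x.data).reshape(B * T, I)
    # input contribution precomputed as one flattened GEMM
    xw = (x2 @ wx.data + b.data).reshape(B, T, 4 * H)
    hs, gates = lstm_scan_forward(xw, wh.data, tied_input_candidate)

    def backward(gout):
        dxw, dwh = lstm_scan_backward(gout, hs, gates, wh.data,
                                      tied_input_candidate)
        dxw2 = dxw.reshape(B * T, 4 * H)
        dx = (dxw2 @ wx.data.T).reshape(B, T, I)
        dwx = x2.T @ dxw2
        db = dxw2.sum(axis=0)
        return dx, dwx, dwh, db

    return _make(hs, (x, wx, wh, b), backward)


def collect_parameters(obj) -> list[Tensor]:
    """Flatten a nested structure (dict/list/Tensor) into trainable tensors."""
    out: list[Tensor] = []

    def walk(o):
        if isinstance(o, Tensor):
            if o.requires_grad:
                out.append(o)
        elif isinstance(o, dict):
            for k in sorted(o):
                walk(o[k])
        elif isinstance(o, (list, tuple)):
            for v in o:
                walk(v)

    walk(obj)
    return out
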