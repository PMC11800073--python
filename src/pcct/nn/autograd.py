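"""Minimal reverse-mode automatic differentiation on numpy arrays.

Every vector-Jacobian product is itself written in terms of the same
primitive ops, so differentiating through a gradient (``create_graph=True``)
works to any order - the Wasserstein gradient penalty needs exactly one such
second-order pass.  The op set is deliberately small: arithmetic,
matmul/reshape/transpose, reductions, gather/scatter (which also power the
im2col convolutions), concat and a few elementwise nonlinearities.
"""
from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextmanager
def set_grad_enabled(mode: bool):
    _GRAD_ENABLED.append(bool(mode))
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _node(data, parents, vjp) -> Tensor:
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        return Tensor(data, True, tuple(parents), vjp)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a cotangent back to the shape of a broadcast operand."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data + b.data, (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(
        a.data * b.data, (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(a, power(b, -1.0))


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    return _node(
        a.data**p, (a,),
        lambda g: (mul(g, mul(_as_tensor(p), power(a, p - 1.0))),),
    )


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g):
        return (mul(g, exp(a)),)

    return _node(out_data, (a,), vjp)


def log(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def abs_(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    sign = Tensor(np.sign(a.data))
    return _node(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    mask = Tensor(np.where(a.data > 0, 1.0, alpha).astype(a.data.dtype))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


# ------------------------------------------------------------ shape plumbing

def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),))


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    inverse = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inverse),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis] = slice(int(lo), int(hi))
            outs.append(slice_(g, tuple(index)))
        return tuple(outs)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def slice_(a: Tensor, index) -> Tensor:
    a = _as_tensor(a)
    old_shape = a.shape

    def vjp(g):
        return (_pad_like(g, old_shape, index),)

    return _node(a.data[index], (a,), vjp)


def _pad_like(g: Tensor, shape, index) -> Tensor:
    # embed a sliced cotangent back into a zero tensor of the original shape
    zeros = Tensor(np.zeros(shape, dtype=g.data.dtype))
    return scatter_slice(zeros, g, index)


def scatter_slice(base: Tensor, patch: Tensor, index) -> Tensor:
    """base with base[index] += patch; differentiable in both operands."""
    base, patch = _as_tensor(base), _as_tensor(patch)
    data = base.data.copy()
    data[index] = data[index] + patch.data
    return _node(data, (base, patch), lambda g: (g, slice_(g, index)))


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    old_shape = a.shape

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * len(old_shape)), old_shape),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(old_shape) for ax in axes)
        if not keepdims:
            kept = list(g.shape)
            for ax in sorted(axes):
                kept.insert(ax, 1)
            g = reshape(g, tuple(kept))
        return (broadcast_to(g, old_shape),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    return _node(
        np.broadcast_to(a.data, shape).copy(), (a,), lambda g: (_unbroadcast(g, old),)
    )


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), _as_tensor(1.0 / float(n)))


# -------------------------------------------------------------------- matmul

def _reduce_to_shape(g: Tensor, shape) -> Tensor:
    while g.ndim > len(shape):
        g = sum_(g, axis=0)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        bt_axes = tuple(range(b.ndim - 2)) + (b.ndim - 1, b.ndim - 2)
        at_axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
        ga = _reduce_to_shape(matmul(g, transpose(b, bt_axes)), a.shape)
        gb = _reduce_to_shape(matmul(transpose(a, at_axes), g), b.shape)
        return (ga, gb)

    return _node(np.matmul(a.data, b.data), (a, b), vjp)


# ----------------------------------------------------------- gather / scatter

def gather_cols(a: Tensor, idx: np.ndarray) -> Tensor:
    """a: (B, N) -> (B, len(idx)); duplicate indices allowed."""
    a = _as_tensor(a)
    n = a.shape[1]
    idx = np.asarray(idx, dtype=np.int64)
    return _node(a.data[:, idx], (a,), lambda g: (scatter_cols(g, idx, n),))


_SCATTER_CACHE: dict[tuple, tuple] = {}


def _scatter_matrix(idx: np.ndarray, n: int):
    """Cached sparse (len(idx), n) one-hot matrix so scatter-add is a matmul."""
    key = (id(idx), idx.shape[0], n)
    hit = _SCATTER_CACHE.get(key)
    if hit is not None:
        return hit[1]
    from scipy import sparse

    m = idx.shape[0]
    mat = sparse.csr_matrix(
        (np.ones(m, np.float32), (np.arange(m), idx)), shape=(m, n)
    )
    _SCATTER_CACHE[key] = (idx, mat)  # hold idx so its id stays unique
    return mat


def scatter_cols(a: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """a: (B, M) scattered (add) into (B, n) at columns idx."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)
    out = np.asarray(a.data @ _scatter_matrix(idx, n))
    return _node(out, (a,), lambda g: (gather_cols(g, idx),))


# ------------------------------------------------------------------ softmax

def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shift = Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(a - shift)
    return div(e, sum_(e, axis=axis, keepdims=True))


# ------------------------------------------------------------------ backward

def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Cotangents of `output` with respect to each tensor in `inputs`.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes and can be differentiated again.
    """
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited or not node.requires_grad:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for parent in node._parents:
            if parent.requires_grad and id(parent) not in visited:
                stack.append((parent, False))

    cotangents: dict[int, Tensor] = {id(output): grad_output}
    with set_grad_enabled(create_graph):
        for node in reversed(topo):
            g = cotangents.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                held = cotangents.get(id(parent))
                cotangents[id(parent)] = pg if held is None else add(held, pg)
        results = []
        for t in inputs:
            got = cotangents.get(id(t))
            results.append(got if got is not None else Tensor(np.zeros_like(t.data)))
    return results
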