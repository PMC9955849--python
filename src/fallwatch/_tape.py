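"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective couples a Gaussian-mixture evidence lower bound with a
feature-gating attention block, and its gradients flow through reparameterized
draws (location-scale Gaussians, Bartlett factors, normalized Gamma
surrogates) as well as closed-form Kullback-Leibler terms with digamma /
log-gamma factors.  This module provides just the operations that graph
needs: broadcast-aware elementwise arithmetic, batched matmul, reductions,
basic indexing, and the special functions.  Everything is float64 and
single-threaded, so identical seeds give bit-identical results.

The vector-Jacobian products are exercised against central finite differences
in the test suite; nothing here is approximate beyond ordinary floating point.
"""

from __future__ import annotations

from typing import Callable, Iterable, Tuple

import numpy as np
from scipy import special as _sp

Array = np.ndarray


class Var:
    """A node in the computation graph: a value plus parent back-links."""

    __slots__ = ("v", "_parents", "grad")

    def __init__(self, value, parents: Tuple = ()):  # parents: ((Var, vjp), ...)
        self.v = np.asarray(value, dtype=np.float64)
        self._parents = parents
        self.grad: Array | None = None

    @property
    def shape(self):
        return self.v.shape

    @property
    def ndim(self):
        return self.v.ndim

    # arithmetic sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.v.shape})"


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _unbroadcast(g: Array, shape: Tuple[int, ...]) -> Array:
    """Sum a gradient down to ``shape`` (the adjoint of numpy broadcasting)."""
    g = np.asarray(g, dtype=np.float64)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, n in enumerate(shape):
        if n == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# binary elementwise ------------------------------------------------------

def add(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.v + b.v,
        (
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(g, b.shape)),
        ),
    )


def sub(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.v - b.v,
        (
            (a, lambda g: _unbroadcast(g, a.shape)),
            (b, lambda g: _unbroadcast(-g, b.shape)),
        ),
    )


def mul(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.v * b.v,
        (
            (a, lambda g: _unbroadcast(g * b.v, a.shape)),
            (b, lambda g: _unbroadcast(g * a.v, b.shape)),
        ),
    )


def div(a, b) -> Var:
    a, b = as_var(a), as_var(b)
    return Var(
        a.v / b.v,
        (
            (a, lambda g: _unbroadcast(g / b.v, a.shape)),
            (b, lambda g: _unbroadcast(-g * a.v / (b.v * b.v), b.shape)),
        ),
    )


def matmul(a, b) -> Var:
    """Batched matrix product; both operands must be at least 2-d."""
    a, b = as_var(a), as_var(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires operands with ndim >= 2")
    return Var(
        a.v @ b.v,
        (
            (a, lambda g: _unbroadcast(g @ np.swapaxes(b.v, -1, -2), a.shape)),
            (b, lambda g: _unbroadcast(np.swapaxes(a.v, -1, -2) @ g, b.shape)),
        ),
    )


# unary elementwise -------------------------------------------------------

def vexp(x) -> Var:
    x = as_var(x)
    val = np.exp(x.v)
    return Var(val, ((x, lambda g: g * val),))


def vlog(x) -> Var:
    x = as_var(x)
    return Var(np.log(x.v), ((x, lambda g: g / x.v),))


def vsqrt(x) -> Var:
    x = as_var(x)
    val = np.sqrt(x.v)
    return Var(val, ((x, lambda g: g * 0.5 / val),))


def vsquare(x) -> Var:
    x = as_var(x)
    return Var(x.v * x.v, ((x, lambda g: g * 2.0 * x.v),))


def vsoftplus(x) -> Var:
    x = as_var(x)
    return Var(np.logaddexp(0.0, x.v), ((x, lambda g: g * _sp.expit(x.v)),))


def vgammaln(x) -> Var:
    x = as_var(x)
    return Var(_sp.gammaln(x.v), ((x, lambda g: g * _sp.digamma(x.v)),))


def vdigamma(x) -> Var:
    x = as_var(x)
    return Var(_sp.digamma(x.v), ((x, lambda g: g * _sp.polygamma(1, x.v)),))


# shape ops ---------------------------------------------------------------

def vreshape(x, shape) -> Var:
    x = as_var(x)
    return Var(x.v.reshape(shape), ((x, lambda g: np.asarray(g).reshape(x.shape)),))


def vswapaxes(x, a: int, b: int) -> Var:
    x = as_var(x)
    return Var(np.swapaxes(x.v, a, b), ((x, lambda g: np.swapaxes(g, a, b)),))


def vtake(x, idx) -> Var:
    """Basic / advanced indexing with scatter-add backward."""
    x = as_var(x)

    def vjp(g):
        out = np.zeros_like(x.v)
        np.add.at(out, idx, g)
        return out

    return Var(x.v[idx], ((x, vjp),))


# reductions --------------------------------------------------------------

def vsum(x, axis=None, keepdims: bool = False) -> Var:
    x = as_var(x)
    val = x.v.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g, dtype=np.float64)
        if axis is None:
            return np.broadcast_to(g, x.shape).astype(np.float64, copy=True)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, x.shape).astype(np.float64, copy=True)

    return Var(val, ((x, vjp),))


def vmean(x, axis=None, keepdims: bool = False) -> Var:
    x = as_var(x)
    if axis is None:
        n = x.v.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([x.shape[a] for a in axes]))
    return mul(vsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


# composites --------------------------------------------------------------

def vsoftmax(x, axis: int = -1) -> Var:
    x = as_var(x)
    m = np.max(x.v, axis=axis, keepdims=True)  # detached; exact for softmax
    e = vexp(sub(x, m))
    return div(e, vsum(e, axis=axis, keepdims=True))


def vlogsumexp(x, axis: int = -1) -> Var:
    x = as_var(x)
    m = np.max(x.v, axis=axis, keepdims=True)
    out = add(vlog(vsum(vexp(sub(x, m)), axis=axis)), np.squeeze(m, axis=axis))
    return out


# backward ----------------------------------------------------------------

def backward(out: Var) -> None:
    """Accumulate gradients of ``out`` (summed if non-scalar) into ``.grad``."""
    topo: list[Var] = []
    visited: set[int] = set()
    stack: list[tuple[Var, bool]] = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in visited:
                stack.append((parent, False))

    out.grad = np.ones_like(out.v)
    for node in reversed(topo):
        if node.grad is None or not node._parents:
            continue
        for parent, vjp in node._parents:
            g = vjp(node.grad)
            parent.grad = g if parent.grad is None else parent.grad + g
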