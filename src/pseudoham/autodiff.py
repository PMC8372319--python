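"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the message-passing encoder and the
pseudo-Hamiltonian head need, including a differentiable symmetric
eigendecomposition: because the loss depends on eigenvalues only, the
backward pass is the exact analytic Jacobian ∂ε_i/∂H = u_i u_iᵀ, i.e.
dL/dH = U diag(dL/dε) Uᵀ. This is well defined even at degeneracies when the
incoming gradients within a degenerate cluster coincide (the expression is
then invariant to the arbitrary eigenvector rotation); near-degenerate
encounters are counted in ``DEGENERACY_COUNTER`` for observability.

Float64 throughout. Not a general tensor library: 1-D/2-D/3-D arrays,
numpy-style broadcasting on elementwise ops, 2-D matmul.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "gather_rows",
    "segment_sum",
    "shifted_softplus",
    "tsum",
    "tmean",
    "sort_last",
    "symmetric_from_triu",
    "eigvalsh",
    "DEGENERACY_COUNTER",
]

LOG2 = float(np.log(2.0))

#: Count of eigendecompositions whose smallest eigenvalue gap fell below 1e-8.
DEGENERACY_COUNTER = {"count": 0}
DEGENERACY_GAP = 1e-8


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __pow__(self, exponent: int):
        if exponent != 2:
            raise NotImplementedError("only squaring is supported")
        return self * self

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            return (g.reshape(old),)

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    # -- backward pass ----------------------------------------------------
    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)

    def backward(g):
        return g @ b.data.T, a.data.T @ g

    return Tensor._make(a.data @ b.data, (a, b), backward)


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]`` (embedding lookup / edge gathering)."""
    idx = np.asarray(idx, dtype=int)

    def backward(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor._make(t.data[idx], (t,), backward)


def segment_sum(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets (message aggregation)."""
    segments = np.asarray(segments, dtype=int)
    data = np.zeros((n_segments,) + t.data.shape[1:])
    np.add.at(data, segments, t.data)

    def backward(g):
        return (g[segments],)

    return Tensor._make(data, (t,), backward)


def shifted_softplus(t: Tensor) -> Tensor:
    """ln(0.5·eˣ + 0.5) = softplus(x) − ln 2; smooth, ssp(0) = 0."""
    data = np.logaddexp(t.data, 0.0) - LOG2
    sig = np.exp(t.data - np.logaddexp(t.data, 0.0))  # overflow-safe sigmoid

    def backward(g):
        return (g * sig,)

    return Tensor._make(data, (t,), backward)


def tsum(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    shape = t.shape

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, shape).copy(),)
        g_exp = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g_exp, shape).copy(),)

    return Tensor._make(t.data.sum(axis=axis, keepdims=keepdims), (t,), backward)


def tmean(t: Tensor) -> Tensor:
    return tsum(t) / t.data.size


def sort_last(t: Tensor) -> Tensor:
    """Sort along the last axis; gradients flow back through the permutation."""
    order = np.argsort(t.data, axis=-1, kind="stable")

    def backward(g):
        out = np.empty_like(g)
        np.put_along_axis(out, order, g, axis=-1)
        return (out,)

    return Tensor._make(np.take_along_axis(t.data, order, axis=-1), (t,), backward)


def symmetric_from_triu(t: Tensor, n: int) -> Tensor:
    """Map (..., n(n+1)/2) upper-triangle entries to exactly symmetric (..., n, n).

    Symmetry holds bitwise because each off-diagonal pair is written from the
    same memory location.
    """
    iu, ju = np.triu_indices(n)
    batch = t.data.shape[:-1]
    H = np.zeros(batch + (n, n))
    H[..., iu, ju] = t.data
    H[..., ju, iu] = t.data

    def backward(g):
        off = iu != ju
        grad = g[..., iu, ju].copy()
        grad[..., off] += g[..., ju[off], iu[off]]
        return (grad,)

    return Tensor._make(H, (t,), backward)


def eigvalsh(t: Tensor) -> Tensor:
    """Ascending eigenvalues of symmetric (..., n, n) with analytic backward.

    Forward uses LAPACK via ``np.linalg.eigh``; backward is
    dL/dH = U diag(dL/dε) Uᵀ, the exact gradient for simple eigenvalues and a
    valid subgradient at degeneracies (exact whenever the incoming gradient is
    constant on each degenerate cluster).
    """
    if not np.allclose(t.data, np.swapaxes(t.data, -1, -2), atol=1e-12):
        raise ValueError("eigvalsh requires a symmetric matrix")
    w, U = np.linalg.eigh(t.data)
    if w.shape[-1] > 1 and np.min(np.diff(w, axis=-1)) < DEGENERACY_GAP:
        DEGENERACY_COUNTER["count"] += 1

    def backward(g):
        return (np.einsum("...ik,...k,...jk->...ij", U, g, U),)

    return Tensor._make(w, (t,), backward)
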