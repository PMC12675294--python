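"""Minimal reverse-mode automatic differentiation over numpy arrays.

The velocity-field network is a small coordinate MLP whose loss is
backpropagated through an unrolled ODE integrator, nearest-neighbour
selections and entropic optimal-transport values.  A tape of ``Var``
nodes with explicit vector-Jacobian products covers exactly the ops
this pipeline needs; everything is float64 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "var",
    "concat",
    "take_rows",
    "leaky_relu",
    "sin",
    "cos",
    "clip01",
    "custom_op",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the computation tape: float64 array + accumulated gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Var, ...] = ()
        self._vjp = None  # callable(out_grad) -> tuple of parent grads

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Var":
        out = Var(data, any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        o = as_var(other)
        return Var._make(
            self.data + o.data,
            (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Var._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_var(other))

    def __rsub__(self, other):
        return as_var(other) + (-self)

    def __mul__(self, other):
        o = as_var(other)
        return Var._make(
            self.data * o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.data.shape),
                _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_var(other)
        return Var._make(
            self.data / o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.data.shape),
                _unbroadcast(-g * self.data / o.data**2, o.data.shape),
            ),
        )

    def __pow__(self, p: float):
        assert np.isscalar(p)
        return Var._make(
            self.data**p,
            (self,),
            lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        o = as_var(other)
        return Var._make(
            self.data @ o.data,
            (self, o),
            lambda g: (g @ o.data.T, self.data.T @ g),
        )

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        return Var._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    @property
    def T(self):
        return Var._make(self.data.T, (self,), lambda g: (g.T,))

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Var._make(self.data[idx], (self,), vjp)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Var._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: unrolled integrators make deep graphs
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(node.grad)):
                if pg is None or not parent.requires_grad:
                    continue
                # functional accumulation: vjp outputs may alias out-grads,
                # so never mutate them in place
                parent.grad = pg if parent.grad is None else parent.grad + pg


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def var(x, requires_grad: bool = True) -> Var:
    return Var(x, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# free functions


def concat(vars_: list[Var], axis: int = -1) -> Var:
    vs = [as_var(v) for v in vars_]
    sizes = [v.data.shape[axis] for v in vs]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Var._make(np.concatenate([v.data for v in vs], axis=axis), vs, vjp)


def take_rows(x: Var, idx: np.ndarray) -> Var:
    """Row gather with scatter-add backward (nearest-neighbour selection)."""
    x = as_var(x)
    idx = np.asarray(idx)

    def vjp(g):
        out = np.zeros_like(x.data)
        np.add.at(out, idx, g)
        return (out,)

    return Var._make(x.data[idx], (x,), vjp)


def leaky_relu(x: Var, slope: float = 0.2) -> Var:
    x = as_var(x)
    mask = np.where(x.data > 0, 1.0, slope)
    return Var._make(x.data * mask, (x,), lambda g: (g * mask,))


def sin(x: Var) -> Var:
    x = as_var(x)
    return Var._make(np.sin(x.data), (x,), lambda g: (g * np.cos(x.data),))


def cos(x: Var) -> Var:
    x = as_var(x)
    return Var._make(np.cos(x.data), (x,), lambda g: (-g * np.sin(x.data),))


def clip01(x: Var) -> Var:
    """Clamp to [0, 1]; zero gradient outside (used for code-grid lookups)."""
    x = as_var(x)
    mask = ((x.data >= 0.0) & (x.data <= 1.0)).astype(np.float64)
    return Var._make(np.clip(x.data, 0.0, 1.0), (x,), lambda g: (g * mask,))


def custom_op(value, parents: tuple, vjp) -> Var:
    """Wrap an externally computed value with a hand-written VJP.

    Used for the entropic optimal-transport value, whose gradient with
    respect to the point positions follows from the converged transport
    plan (Danskin's theorem) rather than from unrolling the solver.
    """
    return Var._make(value, tuple(as_var(p) for p in parents), vjp)
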