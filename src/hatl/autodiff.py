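"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order derivatives: every backward rule is itself expressed in
terms of traced tensor operations, so gradients are graph nodes and can be
differentiated again. This is what the Wasserstein-GAN gradient penalty needs
(the critic loss contains the norm of a gradient, and training differentiates
that norm with respect to the critic weights).

Only the primitives required by the adversarial networks are implemented:
affine maps, elementwise nonlinearities, reductions, concatenation/slicing and
broadcasting. Arrays are float64 throughout; determinism is inherited from
numpy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "grad", "sigmoid", "softplus"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "_vjp")

    def __init__(self, data, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        # _vjp maps the upstream gradient (a Tensor) to a tuple of gradient
        # Tensors aligned with ``parents``; None marks a leaf.
        self._vjp = vjp

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            (self, other),
            lambda g: (_sum_to(g, self.shape), _sum_to(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            (self, other),
            lambda g: (_sum_to(g * other, self.shape), _sum_to(g * self, other.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        # Constant exponent only; sufficient for squares, roots, reciprocals.
        out = Tensor(
            self.data ** exponent,
            (self,),
            lambda g: (g * (exponent * self ** (exponent - 1.0)),),
        )
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.T, self.T @ g),
        )

    @property
    def T(self):
        return Tensor(self.data.T, (self,), lambda g: (g.T,))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.shape

        def vjp(g):
            if axis is None:
                return (_broadcast(g, shape),)
            gd = g
            if not keepdims:
                gd = _expand(gd, axis, shape)
            return (_broadcast(gd, shape),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -----------------------------------------------------
    def relu(self):
        mask = Tensor((self.data > 0).astype(np.float64))
        return self * mask

    def leaky_relu(self, slope: float = 0.2):
        mask = Tensor(np.where(self.data > 0, 1.0, slope))
        return self * mask

    def log(self):
        return Tensor(np.log(self.data), (self,), lambda g: (g * self ** -1.0,))

    def exp(self):
        out_data = np.exp(self.data)
        out = Tensor(out_data, (self,), None)
        out._vjp = lambda g: (g * out,)
        return out

    def sqrt(self):
        return self ** 0.5

    def __getitem__(self, key):
        shape = self.shape

        def vjp(g):
            return (_scatter(g, key, shape),)

        return Tensor(self.data[key], (self,), vjp)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape})"


def tensor(data) -> Tensor:
    return Tensor(data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _broadcast(t: Tensor, shape) -> Tensor:
    if t.shape == tuple(shape):
        return t
    return Tensor(
        np.broadcast_to(t.data, shape).copy(),
        (t,),
        lambda g: (_sum_to(g, t.shape),),
    )


def _sum_to(t: Tensor, shape) -> Tensor:
    """Reduce ``t`` down to ``shape`` by summing broadcast axes."""
    shape = tuple(shape)
    if t.shape == shape:
        return t
    out = t
    while out.ndim > len(shape):
        out = out.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and out.shape[ax] != 1:
            out = out.sum(axis=ax, keepdims=True)
    return out


def _expand(t: Tensor, axis, shape) -> Tensor:
    """Re-insert a reduced axis with keepdims semantics."""
    new_shape = list(t.shape)
    new_shape.insert(axis if axis >= 0 else len(shape) + axis, 1)
    return _reshape(t, new_shape)


def _reshape(t: Tensor, shape) -> Tensor:
    old = t.shape
    return Tensor(t.data.reshape(shape), (t,), lambda g: (_reshape(g, old),))


def _scatter(g: Tensor, key, shape) -> Tensor:
    """Embed a slice gradient into a zero array of the parent's shape."""

    def vjp(h):
        return (h[key],)

    out = np.zeros(shape)
    out[key] = g.data
    return Tensor(out, (g,), vjp)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(lo), int(hi))
            grads.append(g[tuple(key)])
        return tuple(grads)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-t.data))
    out = Tensor(out_data, (t,), None)
    out._vjp = lambda g: (g * (out * (1.0 - out)),)
    return out


def softplus(t: Tensor) -> Tensor:
    """log(1 + exp(t)), computed stably; used for the CGAN log-losses."""
    data = np.logaddexp(0.0, t.data)
    return Tensor(data, (t,), lambda g: (g * sigmoid(t),))


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order  # parents before children


def grad(output: Tensor, inputs) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    The returned gradients are themselves graph nodes, so they can appear in
    later losses and be differentiated again (double backprop).
    """
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")
    order = _toposort(output)
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(order):
        g = grads.get(id(node))
        if g is None or node._vjp is None:
            continue
        for parent, pg in zip(node.parents, node._vjp(g)):
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else acc + pg
    out = []
    for inp in inputs:
        g = grads.get(id(inp))
        out.append(g if g is not None else Tensor(np.zeros_like(inp.data)))
    return out
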