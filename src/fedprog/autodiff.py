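"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine in the style of micrograd/autograd, sized for the small
recurrent models used in this package: float64 arrays, full-graph backward,
no in-place mutation of tracked values. Every primitive's vector-Jacobian
product is exercised against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "stack", "concat", "masked_softmax",
           "rowwise_linear", "rowwise_context_linear", "gelu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")
    __array_priority__ = 100  # beat np.ndarray in mixed arithmetic

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._vjp = None  # callable(grad_out) -> tuple of parent grads

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.data.shape),
                       _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.data.shape),
                       _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.data.shape),
                       _unbroadcast(-g * self.data / other.data ** 2,
                                    other.data.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def vjp(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k, n)
                return b @ g, np.multiply.outer(a, g)
            if b.ndim == 1:  # (..., m, k) @ (k,)
                ga = _unbroadcast(g[..., :, None] * b, a.shape)
                gb = _unbroadcast((g[..., :, None] * a).sum(
                    tuple(range(a.ndim - 1))), b.shape)
                return ga, gb
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(out, (self, other), vjp)

    def __pow__(self, p: float):
        assert isinstance(p, (int, float))
        return Tensor._make(
            self.data ** p, (self,),
            lambda g: (g * p * self.data ** (p - 1),))

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(self.data.shape),))

    def transpose(self, *axes):
        axes = axes or None
        inv = np.argsort(axes) if axes else None
        return Tensor._make(
            np.transpose(self.data, axes), (self,),
            lambda g: (np.transpose(g, inv),))

    def __getitem__(self, idx):
        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return Tensor._make(self.data[idx], (self,), vjp)

    # -- nonlinearities ---------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g: (g * (1 - t * t),))

    def exp(self):
        e = np.exp(self.data)
        return Tensor._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the bounds."""
        inside = (self.data >= lo) & (self.data <= hi)
        return Tensor._make(np.clip(self.data, lo, hi), (self,),
                            lambda g: (g * inside,))

    def where(self, mask: np.ndarray, other):
        """mask ? self : other — the untaken branch gets an exactly-zero grad."""
        other = as_tensor(other)
        mask = np.asarray(mask, dtype=bool)
        return Tensor._make(
            np.where(mask, self.data, other.data), (self, other),
            lambda g: (_unbroadcast(np.where(mask, g, 0.0), self.data.shape),
                       _unbroadcast(np.where(mask, 0.0, g), other.data.shape)))

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:  # iterative DFS (graphs can be thousands of nodes deep)
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None and node.requires_grad and node._vjp is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def vjp(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._make(out, tensors, vjp)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, vjp)


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax along `axis` with hard suppression where ``mask`` is False.

    Masked positions get probability exactly 0 (not merely tiny) and an
    exactly-zero gradient, implementing the freeze-and-mask contract.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), scores.data.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_softmax: some slice has no unmasked entry")
    neg = np.where(mask, scores.data, -np.inf)
    z = neg - neg.max(axis=axis, keepdims=True)
    e = np.where(mask, np.exp(z), 0.0)
    p = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        return (np.where(mask, p * (g - dot), 0.0),)

    return Tensor._make(p, (scores,), vjp)


def rowwise_linear(W: Tensor, F: Tensor) -> Tensor:
    """Per-row linear maps: out[..., r, i] = sum_j W[r, i, j] * F[..., r, j].

    `W` has shape (R, h, h); `F` has shape (..., R, h). Used for the per-row
    key/value projections of the recalibration attention.
    """
    out = np.einsum("rij,...rj->...ri", W.data, F.data, optimize=True)

    def vjp(g):
        gW = np.einsum("...ri,...rj->rij", g, F.data, optimize=True)
        gF = np.einsum("rij,...ri->...rj", W.data, g, optimize=True)
        return gW, gF

    return Tensor._make(out, (W, F), vjp)


def rowwise_context_linear(W: Tensor, c: Tensor) -> Tensor:
    """Per-row linear maps of one shared context: out[..., r, i] = W[r] @ c.

    `W` has shape (R, h, h); `c` has shape (..., h); output (..., R, h).
    """
    out = np.einsum("rij,...j->...ri", W.data, c.data, optimize=True)

    def vjp(g):
        gW = np.einsum("...ri,...j->rij", g, c.data, optimize=True)
        gc = np.einsum("rij,...ri->...j", W.data, g, optimize=True)
        return gW, gc

    return Tensor._make(out, (W, c), vjp)


def rowdot(a: Tensor, b: Tensor) -> Tensor:
    """out[..., r] = a[..., r, :] . b[..., r, :] (fused score product)."""
    out = np.einsum("...ri,...ri->...r", a.data, b.data, optimize=True)

    def vjp(g):
        ge = g[..., None]
        return ge * b.data, ge * a.data

    return Tensor._make(out, (a, b), vjp)


def weighted_row_sum(w: Tensor, v: Tensor) -> Tensor:
    """out[..., h] = sum_r w[..., r] * v[..., r, h] (fused convex combination)."""
    out = np.einsum("...r,...rh->...h", w.data, v.data, optimize=True)

    def vjp(g):
        gw = np.einsum("...h,...rh->...r", g, v.data, optimize=True)
        gv = w.data[..., None] * g[..., None, :]
        return gw, gv

    return Tensor._make(out, (w, v), vjp)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    u = _GELU_C * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    out = 0.5 * x.data * (1.0 + t)

    def vjp(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x.data ** 2)
        return (g * (0.5 * (1.0 + t) + 0.5 * x.data * (1 - t * t) * du),)

    return Tensor._make(out, (x,), vjp)
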