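"""Minimal reverse-mode automatic differentiation over numpy arrays.

The reconstruction network is small (a handful of dense projections,
row-softmax attention and an MLP decoder trained full-batch), so rather than
pulling in a deep-learning framework the package tracks gradients through a
thin ``Tensor`` wrapper exposing exactly the operations the model and its
losses need: (broadcasting) arithmetic, matmul, transpose, LeakyReLU,
row-wise softmax, column concatenation/slicing, row gather/scatter and a few
reductions.  Gradients are accumulated by topological-order backpropagation.

Arrays keep their floating dtype (float32 or float64); everything is
deterministic given deterministic inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "div", "matmul", "transpose",
    "leaky_relu", "softmax_rows", "concat_cols", "col_slice", "gather_rows",
    "scatter_rows", "sum_all", "mean_all", "sum_axis0", "mean_last2", "sqrt", "clamp_min",
]


class PartialGrad:
    """A gradient contribution covering only a slice of the parent array.

    Emitted by :func:`col_slice` and :func:`gather_rows` so that backward
    accumulation can add into one shared buffer instead of materializing a
    full-size mostly-zero array per slice.
    """

    __slots__ = ("axis", "index", "g")

    def __init__(self, axis: str, index, g):
        self.axis = axis  # "cols" or "rows"
        self.index = index
        self.g = g


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode gradients."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_vjp",
                 "_grad_owned")

    def __init__(self, value, requires_grad: bool = False):
        v = np.asarray(value)
        if not np.issubdtype(v.dtype, np.floating):
            v = v.astype(np.float64)
        self.value = v
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._vjp = None
        self._grad_owned = False

    # -- conveniences -------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def dtype(self):
        return self.value.dtype

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __float__(self) -> float:
        return float(self.value)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------
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

    @property
    def T(self):
        return transpose(self)

    # -- backprop -----------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output, filling ``grad`` on ancestors."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be a few hundred nodes deep
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
        for t in topo:
            t.grad = None
            t._grad_owned = False
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._vjp is None or t.grad is None:
                continue
            for parent, g in zip(t._parents, t._vjp(t.grad)):
                if g is None or not parent.requires_grad:
                    continue
                _accumulate(parent, g)


def _accumulate(parent: Tensor, g) -> None:
    """Add one vjp contribution to ``parent.grad``.

    Dense contributions may be views of other tensors' gradients, so they
    are only mutated in place once the parent owns a private buffer.
    ``PartialGrad`` contributions always add into an owned buffer.
    """
    if isinstance(g, PartialGrad):
        if parent.grad is None:
            parent.grad = np.zeros_like(parent.value)
            parent._grad_owned = True
        elif not parent._grad_owned:
            parent.grad = parent.grad.copy()
            parent._grad_owned = True
        if g.axis == "cols":
            j0, j1 = g.index
            parent.grad[..., j0:j1] += g.g
        else:
            idx = g.index
            if idx.ndim == 1:
                parent.grad[..., idx, :] += g.g
            else:  # one index row per batch entry
                for b in range(idx.shape[0]):
                    parent.grad[b, idx[b], :] += g.g[b]
        return
    if parent.grad is None:
        parent.grad = g
        parent._grad_owned = False
    elif parent._grad_owned:
        parent.grad += g
    else:
        parent.grad = parent.grad + g
        parent._grad_owned = True


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(value, parents, vjp) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# -- elementwise arithmetic -------------------------------------------------
# Python scalars get a fast path that also preserves the array dtype
# (wrapping them in a float64 Tensor would upcast float32 graphs).

def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) or (np.isscalar(x) and not isinstance(x, str))


def add(a, b) -> Tensor:
    if _is_scalar(b):
        a = as_tensor(a)
        return _make(a.value + b, (a,), lambda g: (g,))
    if _is_scalar(a):
        return add(b, a)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value + b.value, (a, b),
                 lambda g: (_unbroadcast(g, a.shape) if a.requires_grad else None,
                            _unbroadcast(g, b.shape) if b.requires_grad else None))


def sub(a, b) -> Tensor:
    if _is_scalar(b):
        a = as_tensor(a)
        return _make(a.value - b, (a,), lambda g: (g,))
    if _is_scalar(a):
        b = as_tensor(b)
        return _make(a - b.value, (b,), lambda g: (-g,))
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value - b.value, (a, b),
                 lambda g: (_unbroadcast(g, a.shape) if a.requires_grad else None,
                            _unbroadcast(-g, b.shape) if b.requires_grad else None))


def mul(a, b) -> Tensor:
    if _is_scalar(b):
        a = as_tensor(a)
        return _make(a.value * b, (a,), lambda g: (g * b,))
    if _is_scalar(a):
        return mul(b, a)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value * b.value, (a, b),
                 lambda g: (_unbroadcast(g * b.value, a.shape) if a.requires_grad else None,
                            _unbroadcast(g * a.value, b.shape) if b.requires_grad else None))


def div(a, b) -> Tensor:
    if _is_scalar(b):
        return mul(a, 1.0 / b)
    if _is_scalar(a):
        b = as_tensor(b)
        return _make(a / b.value, (b,),
                     lambda g: (-g * a / (b.value ** 2),))
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.value / b.value, (a, b),
                 lambda g: (_unbroadcast(g / b.value, a.shape) if a.requires_grad else None,
                            _unbroadcast(-g * a.value / (b.value ** 2), b.shape) if b.requires_grad else None))


# -- linear algebra ---------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return (g @ np.swapaxes(b.value, -1, -2) if a.requires_grad else None,
                np.swapaxes(a.value, -1, -2) @ g if b.requires_grad else None)

    return _make(a.value @ b.value, (a, b), vjp)


def transpose(a) -> Tensor:
    """Swap the last two axes (plain transpose for 2-D input)."""
    a = as_tensor(a)
    return _make(np.swapaxes(a.value, -1, -2), (a,),
                 lambda g: (np.swapaxes(g, -1, -2),))


# -- nonlinearities ---------------------------------------------------------

def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    # for slope <= 1, LeakyReLU(v) = max(v, slope * v)
    out = np.maximum(a.value, slope * a.value)
    factor = (a.value > 0).astype(a.value.dtype)
    factor *= 1.0 - slope
    factor += slope  # 1 where positive, slope elsewhere
    return _make(out, (a,), lambda g: (g * factor,))


def softmax_rows(a) -> Tensor:
    """Row-wise softmax, stabilized by max subtraction."""
    a = as_tensor(a)
    shifted = a.value - a.value.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)

    def vjp(g):
        inner = (g * s).sum(axis=-1, keepdims=True)
        return (s * (g - inner),)

    return _make(s, (a,), vjp)


# -- shape surgery ----------------------------------------------------------

def concat_cols(tensors) -> Tensor:
    """Concatenate along the last axis."""
    tensors = [as_tensor(t) for t in tensors]
    widths = [t.shape[-1] for t in tensors]
    out = np.concatenate([t.value for t in tensors], axis=-1)
    offsets = np.cumsum([0] + widths)

    def vjp(g):
        return tuple(g[..., offsets[i]:offsets[i + 1]]
                     for i in range(len(tensors)))

    return _make(out, tensors, vjp)


def col_slice(a, j0: int, j1: int) -> Tensor:
    a = as_tensor(a)
    out = np.ascontiguousarray(a.value[..., j0:j1])
    return _make(out, (a,), lambda g: (PartialGrad("cols", (j0, j1), g),))


def gather_rows(a, idx) -> Tensor:
    """Select rows (next-to-last axis).  ``idx`` may be 1-D (shared across
    any leading batch dimension) or 2-D (one index row per batch entry)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    if idx.ndim == 1:
        out = a.value[..., idx, :]
        if idx.size == np.unique(idx).size:
            vjp = lambda g: (PartialGrad("rows", idx, g),)
        else:
            def vjp(g):
                full = np.zeros_like(a.value)
                np.add.at(full, (..., idx, slice(None)), g)
                return (full,)
    else:
        sel = idx[:, :, None]
        out = np.take_along_axis(a.value, sel, axis=-2)
        # per-batch index rows are unique by construction
        vjp = lambda g: (PartialGrad("rows", idx, g),)

    return _make(out, (a,), vjp)


def scatter_rows(a, idx, n_rows: int) -> Tensor:
    """Place the rows of ``a`` at positions ``idx`` of an all-zero matrix;
    inverse of :func:`gather_rows` (same 1-D/2-D index convention)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    shape = a.shape[:-2] + (n_rows, a.shape[-1])
    out = np.zeros(shape, dtype=a.dtype)
    if idx.ndim == 1:
        out[..., idx, :] = a.value
        return _make(out, (a,), lambda g: (g[..., idx, :],))
    sel = idx[:, :, None]
    np.put_along_axis(out, sel, a.value, axis=-2)
    return _make(out, (a,),
                 lambda g: (np.take_along_axis(g, sel, axis=-2),))


# -- reductions -------------------------------------------------------------

def sum_all(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.asarray(a.value.sum()), (a,),
                 lambda g: (np.broadcast_to(g, a.shape).astype(a.dtype),))


def mean_all(a) -> Tensor:
    a = as_tensor(a)
    n = a.value.size
    return _make(np.asarray(a.value.mean()), (a,),
                 lambda g: ((np.broadcast_to(g, a.shape) / n).astype(a.dtype),))


def sum_axis0(a) -> Tensor:
    """Column sums over the next-to-last axis, keepdims:
    (..., n, g) -> (..., 1, g)."""
    a = as_tensor(a)
    return _make(a.value.sum(axis=-2, keepdims=True), (a,),
                 lambda g: (np.broadcast_to(g, a.shape).astype(a.dtype),))


def mean_last2(a) -> Tensor:
    """Mean over the last two axes: (..., n, m) -> (...,)."""
    a = as_tensor(a)
    n = a.shape[-1] * a.shape[-2]

    def vjp(g):
        return ((np.broadcast_to(g[..., None, None], a.shape) / n).astype(a.dtype),)

    return _make(a.value.mean(axis=(-1, -2)), (a,), vjp)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = np.sqrt(a.value)

    def vjp(g):
        return (g * 0.5 / np.maximum(out, 1e-300),)

    return _make(out, (a,), vjp)


def clamp_min(a, floor: float) -> Tensor:
    a = as_tensor(a)
    keep = a.value > floor
    return _make(np.maximum(a.value, floor), (a,),
                 lambda g: (g * keep,))
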