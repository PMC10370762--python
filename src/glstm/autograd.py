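"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (a few thousand parameters), so a compact
tape-based engine is all that is needed to train it.  ``Tensor`` wraps an
``ndarray`` and records a vector-Jacobian product per parent; :meth:`Tensor.backward`
walks the tape in reverse topological order.

The module-level functions (:func:`sigmoid`, :func:`tanh`, :func:`relu`,
:func:`leaky_relu`, :func:`softmax`, :func:`concat`, :func:`mean_all`) dispatch on
type: given plain arrays they compute with numpy and return arrays, given
``Tensor`` they build the tape.  Forward model code written against these
helpers therefore runs identically in pure-numpy inference mode and in
gradient-tracked training mode.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Adam",
    "sigmoid",
    "tanh",
    "relu",
    "leaky_relu",
    "softmax",
    "concat",
    "mean_all",
    "as_array",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entries needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # keep numpy from consuming Tensor operands elementwise; arithmetic with
    # ndarrays must fall back to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        # parents: tuple of (Tensor, vjp) where vjp maps d(out) -> d(parent)
        self._parents = tuple(parents)

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=[(self, lambda g: g.T)])
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        o = _wrap(other)
        return Tensor(
            self.data + o.data,
            parents=[
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        o = _wrap(other)
        return Tensor(
            self.data * o.data,
            parents=[
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _wrap(other)
        return Tensor(
            self.data / o.data,
            parents=[
                (self, lambda g: _unbroadcast(g / o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(-g * self.data / o.data**2, o.data.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor(
            self.data**p,
            parents=[(self, lambda g: g * p * self.data ** (p - 1))],
        )

    def __matmul__(self, other):
        o = _wrap(other)
        a, b = self.data, o.data
        out = a @ b

        def vjp_a(g):
            if b.ndim == 1 and a.ndim == 1:
                return g * b
            if b.ndim == 1:
                return np.outer(g, b) if a.ndim == 2 else g * b
            if a.ndim == 1:
                return g @ b.T
            return g @ b.T

        def vjp_b(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * a
            if a.ndim == 1:
                return np.outer(a, g) if b.ndim == 2 else g * a
            if b.ndim == 1:
                return a.T @ g
            return a.T @ g

        return Tensor(out, parents=[(self, vjp_a), (o, vjp_b)])

    def __rmatmul__(self, other):
        return _wrap(other) @ self

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=[(self, vjp)])

    # -- reductions & elementwise functions -------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=[(self, vjp)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=[(self, lambda g: g.reshape(self.data.shape))],
        )

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out)])

    def log(self):
        return Tensor(np.log(self.data), parents=[(self, lambda g: g / self.data)])

    def sigmoid(self):
        out = _stable_sigmoid(self.data)
        return Tensor(out, parents=[(self, lambda g: g * out * (1.0 - out))])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=[(self, lambda g: g * (1.0 - out**2))])

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        return Tensor(self.data * scale, parents=[(self, lambda g: g * scale)])

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of ``self`` (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, iter(node._parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if id(parent) not in seen:
                        seen.add(id(parent))
                        stack.append((parent, iter(parent._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    # evaluate exp only on the non-overflowing branch
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def as_array(x) -> np.ndarray:
    """Underlying ndarray of ``x``, whether Tensor or array-like."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# dual-mode functional helpers
# ---------------------------------------------------------------------------

def sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    return _stable_sigmoid(np.asarray(x, dtype=np.float64))


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(np.asarray(x, dtype=np.float64))


def relu(x):
    if isinstance(x, Tensor):
        return x.relu()
    x = np.asarray(x, dtype=np.float64)
    return np.maximum(x, 0.0)


def leaky_relu(x, slope: float = 0.2):
    if isinstance(x, Tensor):
        return x.leaky_relu(slope)
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, slope * x)


def softmax(x, axis: int = -1):
    if isinstance(x, Tensor):
        shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)
    x = np.asarray(x, dtype=np.float64)
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def concat(parts, axis: int = -1):
    if any(isinstance(p, Tensor) for p in parts):
        tensors = [_wrap(p) for p in parts]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        data = np.concatenate([t.data for t in tensors], axis=axis)

        def make_vjp(i):
            def vjp(g):
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(offsets[i], offsets[i + 1])
                return g[tuple(sl)]

            return vjp

        return Tensor(data, parents=[(t, make_vjp(i)) for i, t in enumerate(tensors)])
    return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts], axis=axis)


def mean_all(x):
    return x.mean() if isinstance(x, Tensor) else float(np.mean(x))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most ``max_norm``."""
        total = np.sqrt(
            sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
        )
        if total > max_norm > 0:
            scale = max_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
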