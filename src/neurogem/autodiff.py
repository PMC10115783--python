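"""Reverse-mode automatic differentiation over numpy arrays.

The wiring-rule encodings in this package are trained by backpropagating task
loss *through the weight-generation process* into identities, interaction
matrices and spatial gene fields — and, for meta-learning, through unrolled
inner-loop gradient steps (second-order gradients). This module provides the
minimal tensor/graph machinery for that: a :class:`Tensor` wrapping a float64
ndarray, a small set of differentiable primitives, and :func:`grad`.

Backward functions are themselves composed of these primitives, so passing
``create_graph=True`` to :func:`grad` yields gradients that are again
differentiable — which is what makes full (second-order) MAML possible.

Everything is float64. The op set is deliberately small: what the encodings
need (broadcasted arithmetic, batched matmul, reductions, exp/tanh/log/relu,
row gather/scatter for patch extraction and label indexing) and nothing more.
"""

from __future__ import annotations

from contextlib import contextmanager, nullcontext

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph recording inside the block (evaluation, optimizer math)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents: tuple = ()
        self.vjp = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, c):
        return power(self, c)

    def __matmul__(self, other):
        return matmul(self, other)

    @property
    def T(self):
        return swapaxes(self, -1, -2)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out.parents = tuple(parents)
        out.vjp = vjp
    return out


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcasted gradient back to the parent's shape."""
    shape = tuple(shape)
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# -- primitives -----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def power(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)
    return _node(a.data**c, (a,), lambda g: (mul(g, mul(power(a, c - 1.0), c)),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(matmul(g, swapaxes(b, -1, -2)), a.shape)
        gb = _unbroadcast(matmul(swapaxes(a, -1, -2), g), b.shape)
        return ga, gb

    return _node(a.data @ b.data, (a, b), vjp)


def swapaxes(a, i: int, j: int) -> Tensor:
    a = as_tensor(a)
    return _node(np.swapaxes(a.data, i, j), (a,), lambda g: (swapaxes(g, i, j),))


def permute(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(np.transpose(a.data, axes), (a,), lambda g: (permute(g, inv),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    orig = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, orig),))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(
        np.broadcast_to(a.data, shape), (a,), lambda g: (_unbroadcast(g, a.shape),)
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    nd = a.ndim
    if axis is None:
        axes = tuple(range(nd))
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % nd for ax in axes)

    def vjp(g):
        gg = g
        if not keepdims and nd:
            shp = list(a.shape)
            for ax in axes:
                shp[ax] = 1
            gg = reshape(gg, tuple(shp))
        return (broadcast_to(gg, a.shape),)

    return _node(a.data.sum(axis=axes if axis is not None else None, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    nd = a.ndim
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax % nd] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _node(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = _node(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, add(1.0, neg(mul(out, out)))),)
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def maximum_const(a, c: float) -> Tensor:
    """Elementwise max(a, c) with a constant floor; subgradient 1 where a >= c."""
    a = as_tensor(a)
    mask = Tensor((a.data >= c).astype(np.float64))
    return _node(np.maximum(a.data, c), (a,), lambda g: (mul(g, mask),))


def take_rows(a, idx) -> Tensor:
    """Gather rows of ``a`` (first axis) by an integer index array.

    Output shape is ``idx.shape + a.shape[1:]``. The adjoint is a scatter-add,
    itself a linear primitive, so gather/scatter support higher-order grads.
    """
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    n = a.shape[0]
    return _node(a.data[idx], (a,), lambda g: (scatter_rows(g, idx, n),))


def scatter_rows(g, idx, n_rows: int) -> Tensor:
    g = as_tensor(g)
    idx = np.asarray(idx, dtype=np.intp)
    tail = g.shape[idx.ndim :]
    out = np.zeros((n_rows,) + tail)
    np.add.at(out, idx.reshape(-1), g.data.reshape((-1,) + tail))
    return _node(out, (g,), lambda gg: (take_rows(gg, idx),))


# -- losses ---------------------------------------------------------------


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    labels = np.asarray(labels, dtype=np.intp)
    b, c = logits.shape
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant, for stability
    z = logits - shift
    lse = log(tsum(exp(z), axis=1))
    flat = reshape(z, (b * c,))
    picked = take_rows(flat, np.arange(b) * c + labels)
    return tmean(lse - picked)


def softmax_accuracy(logits: Tensor, labels: np.ndarray) -> float:
    pred = np.argmax(logits.data, axis=1)
    return float(np.mean(pred == np.asarray(labels)))


# -- the driver -----------------------------------------------------------


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar (or elementwise-seeded) ``output`` w.r.t. ``inputs``.

    Returns a list of Tensors aligned with ``inputs``; parameters that do not
    influence ``output`` get zero gradients. With ``create_graph=True`` the
    returned gradients carry their own graph and can be differentiated again.
    """
    inputs = list(inputs)
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    keep = {id(t) for t in inputs}
    ctx = nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None:
                continue
            if node.vjp is not None:
                for p, pg in zip(node.parents, node.vjp(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    acc = grads.get(id(p))
                    grads[id(p)] = pg if acc is None else add(acc, pg)
                if id(node) not in keep:
                    del grads[id(node)]
    return [grads.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]


class Adam:
    """Adaptive-moment optimizer over a name → Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        """In-place update from a name → gradient (Tensor or ndarray) dict."""
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            g = g.data if isinstance(g, Tensor) else np.asarray(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
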