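"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run tape: each :class:`Tensor` wraps a float64 ndarray and
remembers the operation that produced it. ``backward``/``grad`` replay the
tape in reverse. Vector-Jacobian products are themselves composed of Tensor
operations, so passing ``create_graph=True`` yields a differentiable gradient
— which is what lets an energy model be trained on its own forces (the loss
contains -dE/dx, and the optimizer needs d(loss)/d(weights) through it).

Only the operations the energy models need are provided: broadcasting
elementwise arithmetic, a handful of smooth nonlinearities, 2-D matmul, a
fixed family of per-head einsum contractions, row gather/scatter (the graph
message-passing primitives) and shape plumbing. Everything runs in float64.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextmanager
def enable_grad():
    _GRAD_ENABLED.append(True)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: "Tensor | None" = None
        self._parents: tuple = ()
        self._vjp = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, key):
        if isinstance(key, (np.ndarray, list)) and np.asarray(key).dtype.kind in "iu":
            return gather(self, np.asarray(key))
        return islice(self, key)

    # -- method forms -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes=None):
        return transpose(self, axes)

    @property
    def T(self):
        return transpose(self, None)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def sqrt(self):
        return sqrt(self)

    def tanh(self):
        return tanh(self)

    def sigmoid(self):
        return sigmoid(self)

    # -- autodiff entry points --------------------------------------------
    def backward(self, gradient: "Tensor | None" = None, create_graph: bool = False):
        """Accumulate d(self)/d(leaf) into ``.grad`` of every reachable leaf."""
        if gradient is None:
            gradient = Tensor(np.ones_like(self.data))
        gmap, tensors = _run_backward(self, gradient, create_graph)
        for tid, t in tensors.items():
            if t._vjp is None and t.requires_grad and tid in gmap:
                g = gmap[tid]
                t.grad = g if t.grad is None else add(t.grad, g)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjp) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


# ---------------------------------------------------------------------------
# backward machinery


def _toposort(root: Tensor):
    order, visited = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p._vjp is not None and id(p) not in visited:
                stack.append((p, False))
    return order  # root is last


def _run_backward(root: Tensor, seed: Tensor, create_graph: bool):
    order = _toposort(root)
    gmap: dict[int, Tensor] = {id(root): seed}
    tensors: dict[int, Tensor] = {id(root): root}
    ctx = enable_grad() if create_graph else no_grad()
    with ctx:
        for node in reversed(order):
            g = gmap.get(id(node))
            if g is None or node._vjp is None:
                continue
            for p, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                tensors[id(p)] = p
                if id(p) in gmap:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    gmap[id(p)] = pg
    return gmap, tensors


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Return d(output)/d(input) for each input, without touching ``.grad``."""
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    gmap, _ = _run_backward(output, grad_output, create_graph)
    out = []
    for t in inputs:
        g = gmap.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out


# ---------------------------------------------------------------------------
# broadcasting helpers


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive operations


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)
        return ga, gb

    return _make(a.data / b.data, (a, b), vjp)


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: (neg(g),))


def power(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _make(a.data**p, (a,), lambda g: (mul(g, mul(Tensor(p), power(a, p - 1.0))),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b, None)), matmul(transpose(a, None), g)),
    )


def transpose(a: Tensor, axes) -> Tensor:
    if axes is None:
        inv = None
    else:
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), (a,), lambda g: (transpose(g, inv),))


# The vjps below recompute the primal (exp, sqrt, ...) from the input rather
# than capturing the output node: capturing the output would create a
# reference cycle (output -> vjp closure -> output) and force every graph to
# wait for the cycle collector. Recomputation keeps graphs acyclic so they
# are freed promptly by reference counting, and keeps higher-order gradients
# exact (the recomputed node still depends on the input).


def exp(a: Tensor) -> Tensor:
    return _make(np.exp(a.data), (a,), lambda g: (mul(g, exp(a)),))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    return _make(np.sqrt(a.data), (a,), lambda g: (div(mul(g, Tensor(0.5)), sqrt(a)),))


def cos(a: Tensor) -> Tensor:
    return _make(np.cos(a.data), (a,), lambda g: (neg(mul(g, sin(a))),))


def sin(a: Tensor) -> Tensor:
    return _make(np.sin(a.data), (a,), lambda g: (mul(g, cos(a)),))


def tanh(a: Tensor) -> Tensor:
    def vjp(g):
        t = tanh(a)
        return (mul(g, sub(Tensor(1.0), mul(t, t))),)

    return _make(np.tanh(a.data), (a,), vjp)


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit

    def vjp(g):
        s = sigmoid(a)
        return (mul(g, mul(s, sub(Tensor(1.0), s))),)

    return _make(expit(a.data), (a,), vjp)


def softplus(a: Tensor) -> Tensor:
    """Numerically stable log(1 + e^x)."""
    return _make(np.logaddexp(0.0, a.data), (a,), lambda g: (mul(g, sigmoid(a)),))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data >= 0.0, 1.0, slope)
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    in_shape = a.shape

    def vjp(g):
        if axis is not None and not keepdims:
            kd_shape = list(in_shape)
            for ax in np.atleast_1d(axis):
                kd_shape[ax] = 1
            g = reshape(g, tuple(kd_shape))
        return (broadcast_to(g, in_shape),)

    return _make(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), vjp)


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return _make(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def reshape(a: Tensor, shape: tuple) -> Tensor:
    in_shape = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, in_shape),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(islice(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


def islice(a: Tensor, key) -> Tensor:
    in_shape = a.shape
    return _make(a.data[key], (a,), lambda g: (scatter_slice(g, key, in_shape),))


def scatter_slice(a: Tensor, key, shape: tuple) -> Tensor:
    out = np.zeros(shape)
    out[key] = a.data
    return _make(out, (a,), lambda g: (islice(g, key),))


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Rows ``a[idx]`` along axis 0; idx is a constant integer array."""
    idx = np.asarray(idx)
    n = a.shape[0]
    return _make(a.data[idx], (a,), lambda g: (scatter_rows(g, idx, n),))


# Scatter plans: np.add.at is an order of magnitude slower than a gather +
# np.add.reduceat over pre-sorted segments. Index arrays are reused across
# many operations and training steps, so the argsort plan is cached per
# array object (strong refs keep ids stable; the cache is bounded).
_SCATTER_PLANS: dict = {}


def _scatter_plan(idx: np.ndarray):
    ent = _SCATTER_PLANS.get(id(idx))
    if ent is not None and ent[0] is idx:
        return ent[1]
    order = np.argsort(idx, kind="stable")
    sorted_idx = idx[order]
    boundaries = np.flatnonzero(np.diff(sorted_idx)) + 1
    starts = np.concatenate([[0], boundaries])
    uniques = sorted_idx[starts]
    if len(_SCATTER_PLANS) > 512:
        _SCATTER_PLANS.clear()
    plan = (order, starts, uniques)
    _SCATTER_PLANS[id(idx)] = (idx, plan)
    return plan


def _scatter_data(values: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n,) + values.shape[1:])
    if len(idx) == 0:
        return out
    order, starts, uniques = _scatter_plan(idx)
    out[uniques] = np.add.reduceat(values[order], starts, axis=0)
    return out


def scatter_rows(a: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """out[idx[p]] += a[p]; the adjoint of :func:`gather` (segment sum)."""
    idx = np.asarray(idx)
    return _make(_scatter_data(a.data, idx, n), (a,), lambda g: (gather(g, idx),))


def affine(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Fused x @ W + b (2-D x); one graph node instead of two."""
    data = x.data @ W.data
    if b is not None:
        data = data + b.data

    def vjp(g):
        gx = matmul(g, transpose(W, None))
        gW = matmul(transpose(x, None), g)
        gb = tsum(g, axis=(0,), keepdims=False) if b is not None else None
        return (gx, gW, gb) if b is not None else (gx, gW)

    parents = (x, W, b) if b is not None else (x, W)
    return _make(data, parents, vjp)


def gauss_rbf(d: Tensor, centers: np.ndarray, gamma: float) -> Tensor:
    """Fused Gaussian radial basis exp(−γ (d − c_k)²) for a 1-D distance array."""
    centers = np.asarray(centers)
    diff = d.data[:, None] - centers
    out_data = np.exp(-gamma * diff * diff)

    def vjp(g):
        # d/dd exp(-γ(d-c)²) = out · (−2γ(d−c)); recomputed to stay acyclic
        dd = reshape(d, (d.shape[0], 1)) - Tensor(centers)
        local = mul(exp(mul(mul(dd, dd), Tensor(-gamma))), mul(dd, Tensor(-2.0 * gamma)))
        return (tsum(mul(g, local), axis=(1,)),)

    return _make(out_data, (d,), vjp)


def pair_distances(pos: Tensor, senders: np.ndarray, receivers: np.ndarray,
                   offsets: np.ndarray) -> Tensor:
    """Fused |pos[s] + offset − pos[r]| per edge; offsets are constants."""
    disp = pos.data[senders] - pos.data[receivers] + offsets
    dist = np.sqrt(np.sum(disp * disp, axis=1))
    n = pos.shape[0]

    def vjp(g):
        unit = Tensor(disp / dist[:, None])
        gd = mul(reshape(g, (len(senders), 1)), unit)
        return (add(scatter_rows(gd, senders, n), scatter_rows(neg(gd), receivers, n)),)

    return _make(dist, (pos,), vjp)


_EINSUM_VJP = {
    "nhd,hde->nhe": (("nhe,hde->nhd", "g", "b"), ("nhd,nhe->hde", "a", "g")),
    "nhe,hde->nhd": (("nhd,hde->nhe", "g", "b"), ("nhd,nhe->hde", "g", "a")),
    "nhd,nhe->hde": (("nhe,hde->nhd", "b", "g"), ("nhd,hde->nhe", "a", "g")),
}


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Per-head batched contractions used by multi-head attention layers."""
    if subscripts not in _EINSUM_VJP:
        raise ValueError(f"unsupported einsum pattern {subscripts!r}")
    (sa, la, ra), (sb, lb, rb) = _EINSUM_VJP[subscripts]

    def vjp(g):
        env = {"a": a, "b": b, "g": g}
        return einsum2(sa, env[la], env[ra]), einsum2(sb, env[lb], env[rb])

    return _make(np.einsum(subscripts, a.data, b.data), (a, b), vjp)


def segment_softmax(scores: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of ``scores`` (P, ...) over rows sharing a segment id.

    The per-segment maximum is subtracted as a constant shift (it does not
    affect the value or the gradient of the softmax).
    """
    segments = np.asarray(segments)
    shift = np.full((n_segments,) + scores.shape[1:], -np.inf)
    np.maximum.at(shift, segments, scores.data)
    e = exp(sub(scores, Tensor(shift[segments])))
    denom = scatter_rows(e, segments, n_segments)
    return div(e, gather(denom, segments))
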