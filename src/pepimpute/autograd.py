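"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the imputation networks need: affine
maps, elementwise nonlinearities, concatenation, row gather, segment
softmax / segment sum (for graph attention over edge lists), reductions,
and an Adam optimizer.  Gradients are checked against central finite
differences in the test suite.

Everything is float64 and deterministic: given the same inputs the same
bit pattern comes out, which the reproducibility contract of the package
relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "matmul",
    "add",
    "sub",
    "mul",
    "neg",
    "relu",
    "leaky_relu",
    "softplus",
    "exp",
    "log",
    "square",
    "concat",
    "reshape",
    "gather_rows",
    "take_flat",
    "segment_softmax",
    "segment_sum",
    "sum_axis",
    "reciprocal",
    "mean_all",
    "sum_all",
    "Adam",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def parameter(data):
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data):
    return Tensor(data, requires_grad=False)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _make(data, parents, backward):
    track = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=parents if track else (), backward=backward if track else None)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope)

    def backward(g):
        _accumulate(a, g * factor)

    return _make(a.data * factor, (a,), backward)


def softplus(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)

    def backward(g):
        sig = 1.0 / (1.0 + np.exp(-a.data))
        _accumulate(a, g * sig)

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def square(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g * 2.0 * a.data)

    return _make(a.data ** 2, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, g.T)

    return _make(a.data.T, (a,), backward)


def _scatter_add_rows(n_rows: int, idx: np.ndarray, g: np.ndarray) -> np.ndarray:
    """bincount-based scatter-add (much faster than np.add.at)."""
    g2 = g.reshape(len(idx), -1)
    out = np.empty((n_rows, g2.shape[1]))
    for c in range(g2.shape[1]):
        out[:, c] = np.bincount(idx, weights=g2[:, c], minlength=n_rows)
    return out.reshape((n_rows,) + g.shape[1:])


def gather_rows(a, idx) -> Tensor:
    """out[k] = a[idx[k]]; duplicate indices accumulate on backward."""
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        _accumulate(a, _scatter_add_rows(a.data.shape[0], idx, g))

    return _make(a.data[idx], (a,), backward)


def take_flat(a, flat_idx) -> Tensor:
    """Select entries of a matrix by flat (C-order) index -> 1-D tensor."""
    a = _as_tensor(a)
    flat_idx = np.asarray(flat_idx, dtype=np.intp)

    def backward(g):
        ga = np.bincount(flat_idx, weights=g, minlength=a.data.size)
        _accumulate(a, ga.reshape(a.data.shape))

    return _make(a.data.reshape(-1)[flat_idx], (a,), backward)


def _run_starts(seg: np.ndarray, num_seg: int):
    """Run-start indices when `seg` is sorted and covers 0..num_seg-1
    contiguously (enables fast reduceat-based segment reductions)."""
    if len(seg) == 0 or seg[0] != 0:
        return None
    d = np.diff(seg)
    if np.any(d < 0):
        return None
    starts = np.concatenate([[0], np.flatnonzero(d) + 1])
    if len(starts) != num_seg:
        return None
    return starts


def segment_softmax(scores, seg, num_seg: int) -> Tensor:
    """Softmax of `scores` (E, ...) over groups defined by seg (E,).

    Used for attention coefficients: entries sharing a segment id
    (the edge's target node) are normalized together, per trailing column.
    """
    scores = _as_tensor(scores)
    seg = np.asarray(seg, dtype=np.intp)
    sorted_runs = _run_starts(seg, num_seg)
    if sorted_runs is not None:
        m = np.maximum.reduceat(scores.data, sorted_runs, axis=0)
        ex = np.exp(scores.data - m[seg])
        denom = np.add.reduceat(ex, sorted_runs, axis=0)
        alpha = ex / denom[seg]

        def backward(g):
            dot = np.add.reduceat(alpha * g, sorted_runs, axis=0)
            _accumulate(scores, alpha * (g - dot[seg]))

    else:
        tail = scores.data.shape[1:]
        m = np.full((num_seg,) + tail, -np.inf)
        np.maximum.at(m, seg, scores.data)
        ex = np.exp(scores.data - m[seg])
        denom = np.zeros((num_seg,) + tail)
        np.add.at(denom, seg, ex)
        alpha = ex / denom[seg]

        def backward(g):
            dot = _scatter_add_rows(num_seg, seg, alpha * g)
            _accumulate(scores, alpha * (g - dot[seg]))

    return _make(alpha, (scores,), backward)


def segment_sum(a, seg, num_seg: int) -> Tensor:
    """out[n] = sum of a[e] over edges e with seg[e] == n."""
    a = _as_tensor(a)
    seg = np.asarray(seg, dtype=np.intp)
    sorted_runs = _run_starts(seg, num_seg)
    if sorted_runs is not None:
        out_data = np.add.reduceat(a.data, sorted_runs, axis=0)
    else:
        out_data = _scatter_add_rows(num_seg, seg, a.data)

    def backward(g):
        _accumulate(a, g[seg])

    return _make(out_data, (a,), backward)


def sum_axis(a, axis: int) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, np.broadcast_to(np.expand_dims(g, axis), a.data.shape).copy())

    return _make(a.data.sum(axis=axis), (a,), backward)


def reciprocal(a) -> Tensor:
    a = _as_tensor(a)
    out_data = 1.0 / a.data

    def backward(g):
        _accumulate(a, -g * out_data * out_data)

    return _make(out_data, (a,), backward)


def sum_all(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(a.data.sum(), (a,), backward)


def mean_all(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size

    def backward(g):
        _accumulate(a, np.broadcast_to(g / n, a.data.shape).copy())

    return _make(a.data.mean(), (a,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay  # decoupled (AdamW-style)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
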