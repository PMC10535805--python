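"""Minimal reverse-mode automatic differentiation on numpy arrays.

The representation-learning stack (sequence CNN, relational GCN/GAT,
fusion, logistic/BCE head) is trained end-to-end with gradient descent.
This module provides exactly the operator set that stack needs: broadcast
arithmetic, matmul, rectifiers, sigmoid/log, concatenation, window
extraction for valid window-3 convolution, an embedding-style gather for
one-hot inputs, pairwise max pooling, masked softmax, row gathers and
reductions — each with a hand-written vector-Jacobian product.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

#: Array dtype for all tensors.  float32 is the training default; the
#: :func:`precision` context switches to float64 when op-level agreement
#: with high-precision oracles is being verified.
DTYPE = np.float32


@contextmanager
def precision(dtype):
    """Temporarily change the tensor dtype (e.g. ``precision('float64')``)."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = old


class Tensor:
    """A numpy array plus gradient buffer and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth is unbounded otherwise
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(
            np.ones_like(self.data) if grad is None else np.asarray(grad)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        out = _node(self.data @ other.data, (self, other))
        a_vec = self.data.ndim == 1
        b_vec = other.data.ndim == 1

        def bwd(g):
            A = self.data[None, :] if a_vec else self.data
            B = other.data[:, None] if b_vec else other.data
            G = g
            if a_vec and b_vec:
                G = np.asarray(g).reshape(1, 1)
            elif a_vec:
                G = g[..., None, :]
            elif b_vec:
                G = g[..., :, None]
            if self.requires_grad:
                ga = G @ np.swapaxes(B, -1, -2)
                if a_vec:
                    ga = ga[..., 0, :]
                    while ga.ndim > 1:
                        ga = ga.sum(axis=0)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(A, -1, -2) @ G
                if b_vec:
                    gb = gb[..., 0]
                    while gb.ndim > 1:
                        gb = gb.sum(axis=0)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if p.requires_grad)
    if not out.requires_grad:
        out._parents = ()
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    out = _node(np.maximum(x.data, 0.0), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    out = _node(np.where(x.data > 0, x.data, slope * x.data), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, slope))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out = _node(s, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def log(x: Tensor) -> Tensor:
    out = _node(np.log(x.data), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = bwd
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the interior."""
    out = _node(np.clip(x.data, lo, hi), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * ((x.data > lo) & (x.data < hi)))

    out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def tsum(x: Tensor, axis=None) -> Tensor:
    out = _node(np.sum(x.data, axis=axis, keepdims=False), (x,))

    def bwd(g):
        if x.requires_grad:
            if axis is None:
                x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            else:
                x._accumulate(np.broadcast_to(np.expand_dims(g, axis), x.data.shape).copy())

    out._backward = bwd
    return out


def mean(x: Tensor, axis=None) -> Tensor:
    n = x.data.size if axis is None else x.data.shape[axis]
    return tsum(x, axis=axis) * (1.0 / n)


def windows3(x: Tensor, axis_len: int | None = None) -> Tensor:
    """Stack the window-3 sliding views of a (..., L, C) tensor into
    (..., L-2, 3*C); the workhorse of valid window-3 convolution."""
    L = x.data.shape[-2]
    if L < 3:
        raise ValueError(f"need length >= 3 for a window-3 convolution, got {L}")
    w = np.concatenate(
        [x.data[..., i : L - 2 + i, :] for i in range(3)], axis=-1
    )
    out = _node(w, (x,))
    C = x.data.shape[-1]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for i in range(3):
                gx[..., i : L - 2 + i, :] += g[..., i * C : (i + 1) * C]
            x._accumulate(gx)

    out._backward = bwd
    return out


def onehot_window_embed(tokens: np.ndarray, W: Tensor) -> Tensor:
    """Window-3 convolution of a one-hot sequence, as an index gather.

    ``tokens``: (B, L) int indices; ``W``: (3, V, N).  Output (B, L-2, N)
    with out[b, p] = sum_w W[w, tokens[b, p+w]] — algebraically identical
    to a window-3 valid convolution applied to the dense one-hot matrix,
    but without materializing V x L inputs.
    """
    B, L = tokens.shape
    if L < 3:
        raise ValueError(f"need length >= 3, got {L}")
    o = np.zeros((B, L - 2, W.data.shape[2]))
    for w in range(3):
        o += W.data[w, tokens[:, w : L - 2 + w]]
    out = _node(o, (W,))

    def bwd(g):
        if W.requires_grad:
            gW = np.zeros_like(W.data)
            for w in range(3):
                np.add.at(gW[w], tokens[:, w : L - 2 + w], g)
            W._accumulate(gW)

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    """Pairwise max pooling along the length axis of (..., L, C); stride 2,
    floor(L/2) outputs (a trailing odd position is dropped)."""
    L = x.data.shape[-2]
    if L < 2:
        raise ValueError(f"need length >= 2 for pooling, got {L}")
    half = L // 2
    a = x.data[..., 0 : 2 * half : 2, :]
    b = x.data[..., 1 : 2 * half : 2, :]
    take_a = a >= b
    out = _node(np.where(take_a, a, b), (x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[..., 0 : 2 * half : 2, :] += g * take_a
            gx[..., 1 : 2 * half : 2, :] += g * ~take_a
            x._accumulate(gx)

    out._backward = bwd
    return out


def masked_max(x: Tensor, mask: np.ndarray, axis: int = -2) -> Tensor:
    """Max over ``axis`` restricted to positions where ``mask`` is True.

    ``mask`` broadcasts against ``x`` (typically (..., L, 1) against
    (..., L, C)).  Rows with no valid position yield 0.
    """
    neg = np.where(mask, x.data, -np.inf)
    m = neg.max(axis=axis)
    any_valid = np.isfinite(m)
    m = np.where(any_valid, m, 0.0)
    out = _node(m, (x,))
    argmax_onehot = (neg == np.expand_dims(np.where(any_valid, m, -np.inf), axis))
    # break ties toward the first position, as np.argmax would
    first = np.cumsum(argmax_onehot, axis=axis) == 1
    argmax_onehot = argmax_onehot & first

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.expand_dims(g, axis) * argmax_onehot)

    out._backward = bwd
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax over positions where ``mask`` (same shape) is True.

    Masked positions get probability 0; all-masked rows return a zero row
    (the neighborless convention — no NaNs).
    """
    z = np.where(mask, logits.data, -np.inf)
    zmax = z.max(axis=-1, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    e = np.where(mask, np.exp(z - zmax), 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    out = _node(p, (logits,))

    def bwd(g):
        if logits.requires_grad:
            gp = g * p
            logits._accumulate(gp - p * gp.sum(axis=-1, keepdims=True))

    out._backward = bwd
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather x[idx] with scatter-add backward."""
    out = _node(x.data[idx], (x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    out._backward = bwd
    return out


class Adam:
    """Adaptive-moment gradient descent (the standard first-order optimizer)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
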