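"""Minimal reverse-mode automatic differentiation on numpy arrays.

The transformer models in this package are small enough to train on a CPU,
so instead of depending on a deep-learning framework the package carries a
compact tape-based autodiff engine with exactly the fused primitives a
vision transformer needs: affine maps, layer normalisation, GELU, scaled
dot-product attention, token gather/scatter and a weighted squared-error
loss. Every primitive's gradient is verified against central finite
differences in the test suite.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the tape in reverse topological order. Wrapping a forward pass
in :func:`no_grad` skips tape construction entirely (used for embedding and
evaluation passes, where it is several times faster).
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Sequence

import numpy as np

from . import _kernels as _k

_grad_enabled: bool = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape construction."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep tapes must not hit recursion limits
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
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def _node(data, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    if _grad_enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- primitives


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out, (a, b), backward)


def add_const(a: Tensor, c: np.ndarray) -> Tensor:
    out = a.data + c

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))

    return _node(out, (a,), backward)


def scale(a: Tensor, s: float) -> Tensor:
    out = a.data * s

    def backward(g):
        _accum(a, g * s)

    return _node(out, (a,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Affine map on the last axis: ``x @ w + b`` for x of shape (..., in)."""
    xd = x.data
    out = xd @ w.data
    if b is not None:
        out = out + b.data

    def backward(g):
        gf = g.reshape(-1, g.shape[-1])
        xf = xd.reshape(-1, xd.shape[-1])
        _accum(w, xf.T @ gf)
        if b is not None:
            _accum(b, gf.sum(axis=0))
        _accum(x, (g @ w.data.T).reshape(xd.shape))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the last axis with affine (1-D) parameters."""
    xd = x.data
    n = xd.shape[-1]
    x2d = np.ascontiguousarray(xd.reshape(-1, n))
    out2d, xhat, inv = _k.layernorm_fwd(x2d, gamma.data, beta.data, eps)

    def backward(g):
        g2d = np.ascontiguousarray(g.reshape(-1, n))
        dx, dgamma, dbeta = _k.layernorm_bwd(g2d, xhat, inv, gamma.data)
        _accum(x, dx.reshape(xd.shape))
        _accum(gamma, dgamma)
        _accum(beta, dbeta)

    return _node(out2d.reshape(xd.shape), (x, gamma, beta), backward)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh formulation).

    Uses the standard 0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x^3)))
    parameterisation, whose gradient is computed exactly for the same
    expression.
    """
    xd = x.data
    flat = np.ascontiguousarray(xd.reshape(-1))
    out, t = _k.gelu_fwd(flat)

    def backward(g):
        dx = _k.gelu_bwd(np.ascontiguousarray(g.reshape(-1)), flat, t)
        _accum(x, dx.reshape(xd.shape))

    return _node(out.reshape(xd.shape), (x,), backward)


def qkv_heads(x: Tensor, heads: int) -> Tensor:
    """Split a packed (batch, T, 3*dim) projection into (3, batch, heads, T, dh)."""
    b, t, d3 = x.data.shape
    d = d3 // 3
    dh = d // heads
    out = x.data.reshape(b, t, 3, heads, dh).transpose(2, 0, 3, 1, 4)

    def backward(g):
        _accum(x, np.ascontiguousarray(g.transpose(1, 3, 0, 2, 4)).reshape(b, t, d3))

    return _node(out, (x,), backward)


def attention_packed(qkv: Tensor) -> Tensor:
    """Scaled dot-product attention over packed (3, batch, heads, T, dh) q/k/v."""
    q, k, v = qkv.data[0], qkv.data[1], qkv.data[2]
    s = 1.0 / math.sqrt(q.shape[-1])
    logits = (q @ np.swapaxes(k, -1, -2)) * s
    logits -= logits.max(axis=-1, keepdims=True)
    a = np.exp(logits)
    a /= a.sum(axis=-1, keepdims=True)
    out = a @ v

    def backward(g):
        dqkv = np.empty_like(qkv.data)
        dqkv[2] = np.swapaxes(a, -1, -2) @ g
        da = g @ np.swapaxes(v, -1, -2)
        dlogits = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dqkv[0] = (dlogits @ k) * s
        dqkv[1] = (np.swapaxes(dlogits, -1, -2) @ q) * s
        _accum(qkv, dqkv)

    return _node(out, (qkv,), backward)


def merge_heads(x: Tensor) -> Tensor:
    """(batch, heads, T, dh) -> (batch, T, heads*dh)."""
    b, h, t, dh = x.data.shape
    out = np.ascontiguousarray(x.data.transpose(0, 2, 1, 3)).reshape(b, t, h * dh)

    def backward(g):
        _accum(x, np.ascontiguousarray(g.reshape(b, t, h, dh).transpose(0, 2, 1, 3)))

    return _node(out, (x,), backward)


def attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Scaled dot-product attention for (batch, heads, tokens, head_dim)."""
    dh = q.data.shape[-1]
    s = 1.0 / math.sqrt(dh)
    logits = (q.data @ np.swapaxes(k.data, -1, -2)) * s
    logits -= logits.max(axis=-1, keepdims=True)
    a = np.exp(logits)
    a /= a.sum(axis=-1, keepdims=True)
    out = a @ v.data

    def backward(g):
        _accum(v, np.swapaxes(a, -1, -2) @ g)
        da = g @ np.swapaxes(v.data, -1, -2)
        dlogits = a * (da - (da * a).sum(axis=-1, keepdims=True))
        _accum(q, (dlogits @ k.data) * s)
        _accum(k, (np.swapaxes(dlogits, -1, -2) @ q.data) * s)

    return _node(out, (q, k, v), backward)


def reshape(x: Tensor, shape: tuple) -> Tensor:
    xshape = x.data.shape
    out = x.data.reshape(shape)

    def backward(g):
        _accum(x, g.reshape(xshape))

    return _node(out, (x,), backward)


def transpose(x: Tensor, axes: tuple) -> Tensor:
    inv = np.argsort(axes)
    out = np.transpose(x.data, axes)

    def backward(g):
        _accum(x, np.transpose(g, inv))

    return _node(out, (x,), backward)


def slice_last(x: Tensor, start: int, stop: int) -> Tensor:
    out = x.data[..., start:stop]

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., start:stop] = g
        _accum(x, full)

    return _node(out, (x,), backward)


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select tokens ``x[:, idx]`` (axis 1); ``idx`` must have unique entries."""
    out = x.data[:, idx]

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, idx] = g
        _accum(x, full)

    return _node(out, (x,), backward)


def prepend_token(x: Tensor, tok: Tensor) -> Tensor:
    """Prepend a learned token (dim,) to every sequence in (batch, T, dim)."""
    b = x.data.shape[0]
    t = np.broadcast_to(tok.data, (b, 1, tok.data.shape[-1]))
    out = np.concatenate([t, x.data], axis=1)

    def backward(g):
        _accum(tok, g[:, 0].sum(axis=0))
        _accum(x, g[:, 1:])

    return _node(out, (x, tok), backward)


def assemble_tokens(visible: Tensor, mask_token: Tensor, vis_idx: np.ndarray, length: int) -> Tensor:
    """Build the full decoder sequence: mask tokens with visible tokens scattered in.

    ``visible`` has shape (batch, n_visible, dim); the result has shape
    (batch, length, dim) with ``mask_token`` at every non-visible position.
    """
    b, _, d = visible.data.shape
    out = np.broadcast_to(mask_token.data, (b, length, d)).copy()
    out[:, vis_idx] = visible.data
    masked_idx = np.setdiff1d(np.arange(length), vis_idx)

    def backward(g):
        _accum(visible, g[:, vis_idx])
        _accum(mask_token, g[:, masked_idx].sum(axis=(0, 1)))

    return _node(out, (visible, mask_token), backward)


def weighted_sq_error(pred: Tensor, target: np.ndarray, weight: np.ndarray, normalizer: float) -> Tensor:
    """``sum(weight * (pred - target)**2) / normalizer`` as a scalar tensor."""
    diff = pred.data - target
    out = np.asarray((weight * diff * diff).sum() / normalizer, dtype=pred.data.dtype)

    def backward(g):
        _accum(pred, (2.0 / normalizer) * weight * diff * g)

    return _node(out, (pred,), backward)
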