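"""Hot elementwise kernels, JIT-compiled with numba when available.

Layer normalisation, GELU and the Adam moment update are the only pieces of
the network whose cost is dominated by Python/numpy dispatch overhead rather
than BLAS time at desk-scale batch sizes, so only these are specialised.
Pure-numpy fallbacks keep the package functional (and the math identical)
without numba.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly by the whole suite
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco

_GELU_C = math.sqrt(2.0 / math.pi)


@njit(cache=True)
def layernorm_fwd(x2d, gamma, beta, eps):
    """Row-wise layernorm of (rows, n); returns (out, xhat, inv_std)."""
    rows, n = x2d.shape
    out = np.empty_like(x2d)
    xhat = np.empty_like(x2d)
    inv = np.empty(rows, dtype=x2d.dtype)
    for r in range(rows):
        mu = 0.0
        for j in range(n):
            mu += x2d[r, j]
        mu /= n
        var = 0.0
        for j in range(n):
            d = x2d[r, j] - mu
            var += d * d
        var /= n
        iv = 1.0 / math.sqrt(var + eps)
        inv[r] = iv
        for j in range(n):
            xh = (x2d[r, j] - mu) * iv
            xhat[r, j] = xh
            out[r, j] = xh * gamma[j] + beta[j]
    return out, xhat, inv


@njit(cache=True)
def layernorm_bwd(g2d, xhat, inv, gamma):
    rows, n = g2d.shape
    dx = np.empty_like(g2d)
    dgamma = np.zeros(n, dtype=g2d.dtype)
    dbeta = np.zeros(n, dtype=g2d.dtype)
    for r in range(rows):
        s1 = 0.0
        s2 = 0.0
        for j in range(n):
            gx = g2d[r, j] * gamma[j]
            s1 += gx
            s2 += gx * xhat[r, j]
            dgamma[j] += g2d[r, j] * xhat[r, j]
            dbeta[j] += g2d[r, j]
        s1 /= n
        s2 /= n
        for j in range(n):
            gx = g2d[r, j] * gamma[j]
            dx[r, j] = (gx - s1 - xhat[r, j] * s2) * inv[r]
    return dx, dgamma, dbeta


@njit(cache=True)
def gelu_fwd(x):
    """Flat tanh-GELU; returns (out, tanh_term) for reuse in the backward pass."""
    out = np.empty_like(x)
    t = np.empty_like(x)
    for i in range(x.size):
        xi = x[i]
        ti = math.tanh(_GELU_C * (xi + 0.044715 * xi * xi * xi))
        t[i] = ti
        out[i] = 0.5 * xi * (1.0 + ti)
    return out, t


@njit(cache=True)
def gelu_bwd(g, x, t):
    dx = np.empty_like(x)
    for i in range(x.size):
        xi = x[i]
        ti = t[i]
        du = _GELU_C * (1.0 + 0.134145 * xi * xi)
        dx[i] = g[i] * (0.5 * (1.0 + ti) + 0.5 * xi * (1.0 - ti * ti) * du)
    return dx


@njit(cache=True)
def adam_update(m, v, g, b1, b2, step_scale, eps):
    """In-place Adam moment update; returns the (flat) parameter decrement."""
    upd = np.empty_like(g)
    for i in range(g.size):
        gi = g[i]
        m[i] = b1 * m[i] + (1.0 - b1) * gi
        v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
        upd[i] = step_scale * m[i] / (math.sqrt(v[i]) + eps)
    return upd


# ------------------------------------------------------- numpy fallbacks

def layernorm_fwd_np(x2d, gamma, beta, eps):
    mu = x2d.mean(axis=1, keepdims=True)
    xc = x2d - mu
    var = (xc * xc).mean(axis=1)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv[:, None]
    return xhat * gamma + beta, xhat, inv


def layernorm_bwd_np(g2d, xhat, inv, gamma):
    gx = g2d * gamma
    dx = (
        gx - gx.mean(axis=1, keepdims=True)
        - xhat * (gx * xhat).mean(axis=1, keepdims=True)
    ) * inv[:, None]
    return dx, (g2d * xhat).sum(axis=0), g2d.sum(axis=0)


def gelu_fwd_np(x):
    t = np.tanh(_GELU_C * (x + 0.044715 * x * x * x))
    return 0.5 * x * (1.0 + t), t


def gelu_bwd_np(g, x, t):
    du = _GELU_C * (1.0 + 0.134145 * x * x)
    return g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)


def adam_update_np(m, v, g, b1, b2, step_scale, eps):
    m *= b1
    m += (1.0 - b1) * g
    v *= b2
    v += (1.0 - b2) * g * g
    return step_scale * m / (np.sqrt(v) + eps)


if not HAVE_NUMBA:  # pragma: no cover
    layernorm_fwd = layernorm_fwd_np
    layernorm_bwd = layernorm_bwd_np
    gelu_fwd = gelu_fwd_np
    gelu_bwd = gelu_bwd_np
    adam_update = adam_update_np
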