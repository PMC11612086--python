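"""Low-level neural-network primitives with hand-written backward passes.

All operations are pure functions on NumPy arrays.  Forward functions return
``(output, cache)``; backward functions take the upstream gradient and the
cache and return the input gradient plus parameter gradients.  Shapes follow
the transformer convention ``(batch, tokens, dim)`` with the feature axis
last.  GELU uses the exact erf form so analytic and finite-difference
gradients agree to high precision.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf

_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def gelu_fwd(x):
    y = 0.5 * x * (1.0 + erf(x / _SQRT2))
    return y, x


def gelu_bwd(dy, cache):
    x = cache
    dgelu = 0.5 * (1.0 + erf(x / _SQRT2)) + x * np.exp(-0.5 * x * x) * _INV_SQRT_2PI
    return dy * dgelu


def softmax(x, axis=-1):
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softmax_bwd(dy, p, axis=-1):
    # d/dx softmax: p * (dy - sum(dy * p))
    s = np.sum(dy * p, axis=axis, keepdims=True)
    return p * (dy - s)


# ---------------------------------------------------------------------------
# linear
# ---------------------------------------------------------------------------

def linear_fwd(x, W, b):
    return x @ W + b, (x, W)


def linear_bwd(dy, cache):
    x, W = cache
    dx = dy @ W.T
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    dW = x2.T @ dy2
    db = dy2.sum(axis=0)
    return dx, dW, db


# ---------------------------------------------------------------------------
# layer norm (over the last axis)
# ---------------------------------------------------------------------------

def layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    y = xhat * g + b
    return y, (xhat, inv, g)


def layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    return dx, dg, db


# ---------------------------------------------------------------------------
# multi-head self-attention
# ---------------------------------------------------------------------------

def _split_heads(x, n_heads, head_dim):
    B, T, _ = x.shape
    return x.reshape(B, T, n_heads, head_dim).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def attention_fwd(x, Wq, bq, Wk, bk, Wv, bv, Wo, bo, n_heads, head_dim):
    """Multi-head self-attention: (B, T, D) -> (B, T, D).

    The q/k/v projections map D -> n_heads*head_dim; the output projection
    maps back to D, so head_dim is decoupled from the model width.
    """
    q, cq = linear_fwd(x, Wq, bq)
    k, ck = linear_fwd(x, Wk, bk)
    v, cv = linear_fwd(x, Wv, bv)
    qh = _split_heads(q, n_heads, head_dim)
    kh = _split_heads(k, n_heads, head_dim)
    vh = _split_heads(v, n_heads, head_dim)
    scale = 1.0 / math.sqrt(head_dim)
    scores = (qh @ kh.transpose(0, 1, 3, 2)) * scale
    attn = softmax(scores, axis=-1)
    oh = attn @ vh
    o = _merge_heads(oh)
    y, co = linear_fwd(o, Wo, bo)
    cache = (cq, ck, cv, co, qh, kh, vh, attn, scale, n_heads, head_dim)
    return y, cache


def attention_bwd(dy, cache):
    cq, ck, cv, co, qh, kh, vh, attn, scale, n_heads, head_dim = cache
    do, dWo, dbo = linear_bwd(dy, co)
    doh = _split_heads(do, n_heads, head_dim)
    dattn = doh @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ doh
    dscores = softmax_bwd(dattn, attn, axis=-1) * scale
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh
    dq = _merge_heads(dqh)
    dk = _merge_heads(dkh)
    dv = _merge_heads(dvh)
    dx_q, dWq, dbq = linear_bwd(dq, cq)
    dx_k, dWk, dbk = linear_bwd(dk, ck)
    dx_v, dWv, dbv = linear_bwd(dv, cv)
    dx = dx_q + dx_k + dx_v
    grads = {
        "Wq": dWq, "bq": dbq, "Wk": dWk, "bk": dbk,
        "Wv": dWv, "bv": dbv, "Wo": dWo, "bo": dbo,
    }
    return dx, grads
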