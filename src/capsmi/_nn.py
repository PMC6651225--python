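"""Low-level differentiable ops (NumPy forward + hand-written backward).

Everything here is batch-first and dtype-preserving.  Convolutions are
"valid" (no padding) and implemented with stride tricks + einsum; the
shapes involved are tiny (14 x 14 images), so this is fast enough for
desk-scale training on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

SELU_SCALE = 1.0507  # lambda in the SELU definition
SELU_ALPHA = 1.6733


# ---------------------------------------------------------------- conv2d

def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1):
    """Valid 2D convolution (cross-correlation). x: (B,C,H,W), w: (F,C,kh,kw).

    Returns (out, cache) with out: (B,F,Ho,Wo).
    """
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("bchwij,fcij->bfhw", win, w, optimize=True) + b[None, :, None, None]
    return out, (x, w, stride)


def conv2d_backward(dout: np.ndarray, cache):
    x, w, stride = cache
    kh, kw = w.shape[2], w.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    dw = np.einsum("bchwij,bfhw->fcij", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.zeros_like(x)
    ho, wo = dout.shape[2], dout.shape[3]
    for i in range(kh):
        for j in range(kw):
            patch = np.einsum("bfhw,fc->bchw", dout, w[:, :, i, j], optimize=True)
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += patch
    return dx, dw, db


# ---------------------------------------------------------------- dense

def dense(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, (x, w)


def dense_backward(dout: np.ndarray, cache):
    x, w = cache
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


# ---------------------------------------------------------------- activations

def selu(x: np.ndarray) -> np.ndarray:
    """Scaled exponential linear unit: lam*x (x>0), lam*a*(e^x - 1) (x<=0)."""
    return np.where(
        x > 0, SELU_SCALE * x, SELU_SCALE * SELU_ALPHA * np.expm1(np.minimum(x, 0.0))
    )


def selu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    grad = np.where(
        x > 0, SELU_SCALE, SELU_SCALE * SELU_ALPHA * np.exp(np.minimum(x, 0.0))
    )
    return dout * grad


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid_backward(dout: np.ndarray, out: np.ndarray) -> np.ndarray:
    return dout * out * (1.0 - out)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Max-stabilized softmax along ``axis``."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(dout: np.ndarray, out: np.ndarray, axis: int = -1) -> np.ndarray:
    return out * (dout - (dout * out).sum(axis=axis, keepdims=True))


# ---------------------------------------------------------------- squash

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """v = (|s|^2 / (1+|s|^2)) * s/|s|; maps 0 -> 0 continuously.

    The output norm is |s|^2/(1+|s|^2), strictly below 1.
    """
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(n2)
    coef = np.where(n > 0, n / (1.0 + n2), 0.0)
    return s * coef


def squash_backward(dout: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(n2)
    coef = np.where(n > 0, n / (1.0 + n2), 0.0)
    # d coef/d n = (1 - n^2) / (1 + n^2)^2 ; chain through n = |s|
    dcoef = (1.0 - n2) / (1.0 + n2) ** 2
    dot = np.sum(dout * s, axis=axis, keepdims=True)
    n_safe = np.where(n > 0, n, 1.0)
    return dout * coef + s * (dot * dcoef / n_safe) * (n > 0)


# ---------------------------------------------------------------- batch norm

def batchnorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
              running: dict, train: bool, momentum: float = 0.1,
              eps: float = 1e-5):
    """Per-channel batch norm for (B, C, H, W) tensors."""
    axes = (0, 2, 3)
    shape = (1, -1, 1, 1)
    if train:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    return out, (xhat, gamma, inv, train)


def batchnorm_backward(dout: np.ndarray, cache):
    xhat, gamma, inv, train = cache
    shape = (1, -1, 1, 1)
    axes = (0, 2, 3)
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma.reshape(shape)
    if not train:
        return dxhat * inv.reshape(shape), dgamma, dbeta
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dx = (inv.reshape(shape) / m) * (
        m * dxhat
        - dxhat.sum(axis=axes).reshape(shape)
        - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
    )
    return dx, dgamma, dbeta
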