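"""Minimal NumPy primitives for 3D convolutional networks.

Forward/backward pairs for 3D convolution (stride 1, 'same' padding for
3x3x3 kernels), batch normalisation, 2x2x2 max pooling with floor
division, ReLU, inverted dropout and fully connected layers.  The
convolution is evaluated as a matrix product over im2col windows,
chunked along the depth axis to bound memory; gradients are exact
(verified against finite differences in the test suite).

Array convention: activations are (N, C, D, H, W); convolution weights
are (C_out, C_in, k, k, k).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Cap on the number of window elements materialised per im2col chunk.
_CHUNK_ELEMENTS = 20_000_000


def _slab(n: int, c: int, h: int, w: int, k: int) -> int:
    per_depth = max(1, n * c * h * w * k**3)
    return max(1, _CHUNK_ELEMENTS // per_depth)


def conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, pad: int) -> np.ndarray:
    """3D cross-correlation, stride 1. Output spatial size D+2p-k+1 etc."""
    N, C, D, H, Wd = x.shape
    Co, Ci, k, _, _ = W.shape
    if C != Ci:
        raise ValueError(f"channel mismatch: input {C}, kernel {Ci}")
    if k == 1 and pad == 0:
        out = np.tensordot(W[:, :, 0, 0, 0], x, axes=([1], [1]))
        out = np.moveaxis(out, 0, 1)
        return out + b.reshape(1, -1, 1, 1, 1)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do, Ho, Wo = (D + 2 * pad - k + 1, H + 2 * pad - k + 1, Wd + 2 * pad - k + 1)
    out = np.empty((N, Co, Do, Ho, Wo), dtype=x.dtype)
    slab = _slab(N, C, Ho, Wo, k)
    for d0 in range(0, Do, slab):
        d1 = min(Do, d0 + slab)
        win = sliding_window_view(xp[:, :, d0 : d1 + k - 1], (k, k, k), axis=(2, 3, 4))
        o = np.tensordot(win, W, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        out[:, :, d0:d1] = np.moveaxis(o, -1, 1)
    return out + b.reshape(1, -1, 1, 1, 1)


def conv3d_backward(
    dout: np.ndarray, x: np.ndarray, W: np.ndarray, pad: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of conv3d_forward."""
    N, C, D, H, Wd = x.shape
    Co, Ci, k, _, _ = W.shape
    db = dout.sum(axis=(0, 2, 3, 4))
    if k == 1 and pad == 0:
        dW = np.tensordot(dout, x, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        dW = dW.reshape(Co, Ci, 1, 1, 1)
        dx = np.tensordot(W[:, :, 0, 0, 0].T, dout, axes=([1], [1]))
        dx = np.moveaxis(dx, 0, 1)
        return dx, dW, db
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Do, Ho, Wo = dout.shape[2:]
    dW = np.zeros_like(W)
    slab = _slab(N, C, Ho, Wo, k)
    for d0 in range(0, Do, slab):
        d1 = min(Do, d0 + slab)
        win = sliding_window_view(xp[:, :, d0 : d1 + k - 1], (k, k, k), axis=(2, 3, 4))
        g = np.tensordot(win, dout[:, :, d0:d1], axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        dW += np.moveaxis(g, -1, 0)  # (C,k,k,k,Co) -> (Co,C,k,k,k)
    # dx: full correlation of dout with the flipped, channel-swapped kernel.
    W_rot = np.ascontiguousarray(np.flip(W, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
    dx = conv3d_forward(dout, W_rot, np.zeros(C, dtype=x.dtype), pad=k - 1 - pad)
    return dx, dW, db


# ---------------------------------------------------------------------------
# Batch normalisation over (N, D, H, W) per channel

def bn_forward(x, gamma, beta, state, train, momentum=0.1, eps=1e-5):
    axes = (0, 2, 3, 4)
    sh = (1, -1, 1, 1, 1)
    if train:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        state["mean"] = (1.0 - momentum) * state["mean"] + momentum * mean
        state["var"] = (1.0 - momentum) * state["var"] + momentum * var
    else:
        mean, var = state["mean"], state["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
    out = gamma.reshape(sh) * xhat + beta.reshape(sh)
    return out, (xhat, inv, gamma, train)


def bn_backward(dout, cache):
    xhat, inv, gamma, train = cache
    axes = (0, 2, 3, 4)
    sh = (1, -1, 1, 1, 1)
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    if train:
        m = dout.size // dout.shape[1]
        dx = (gamma * inv).reshape(sh) / m * (
            m * dout - dbeta.reshape(sh) - xhat * dgamma.reshape(sh)
        )
    else:
        dx = (gamma * inv).reshape(sh) * dout
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# 2x2x2 max pooling (kernel 2, stride 2, floor division, no padding),
# realised as sequential pair-wise maxima along each spatial axis.  Axes
# that have already been reduced to extent 1 pass through unchanged,
# which is what lets small desk-scale grids survive five pooling stages.

def _pool_axis_forward(x, axis):
    s = x.shape[axis]
    if s < 2:
        return x, None
    s2 = (s // 2) * 2
    xm = np.moveaxis(x, axis, -1)
    xr = xm[..., :s2].reshape(*xm.shape[:-1], s2 // 2, 2)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return np.moveaxis(out, -1, axis), (x.shape, axis, s2, arg)


def _pool_axis_backward(dout, cache):
    if cache is None:
        return dout
    shape, axis, s2, arg = cache
    dm = np.moveaxis(dout, axis, -1)
    lead = dm.shape[:-1]
    dr = np.zeros((*lead, s2 // 2, 2), dtype=dout.dtype)
    np.put_along_axis(dr, arg[..., None], dm[..., None], axis=-1)
    s = shape[axis]
    dxm = np.zeros((*lead, s), dtype=dout.dtype)
    dxm[..., :s2] = dr.reshape(*lead, s2)
    return np.moveaxis(dxm, -1, axis)


def maxpool3d_forward(x):
    caches = []
    for axis in (2, 3, 4):
        x, c = _pool_axis_forward(x, axis)
        caches.append(c)
    return x, caches


def maxpool3d_backward(dout, caches):
    for c in reversed(caches):
        dout = _pool_axis_backward(dout, c)
    return dout


# ---------------------------------------------------------------------------
# Pointwise layers

def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def dropout_forward(x, rate, rng, train):
    if not train or rate == 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(dout, mask):
    return dout if mask is None else dout * mask


def linear_forward(x, W, b):
    return x @ W + b, x


def linear_backward(dout, x, W):
    return dout @ W.T, x.T @ dout, dout.sum(axis=0)


# ---------------------------------------------------------------------------
# Adam

class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params, lr=3e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
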