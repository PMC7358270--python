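"""Minimal numpy compute kernels for the 3D segmentation network.

Forward and backward passes for the only four layer types the architecture
needs: valid (unpadded) 3D convolution, 2x2x2 max pooling, 2x2x2 stride-2
transposed convolution, and ReLU, plus the Adam optimizer.  Convolutions
are evaluated as a sum of 27 (kernel-offset) matrix products, which keeps
memory low and routes the arithmetic through BLAS.

Array layout is channels-first without a batch axis: (C, D, H, W).
Gradient correctness is established by finite-difference tests.
"""

from __future__ import annotations

import numpy as np


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 3D convolution (cross-correlation). w: (Cout, Cin, k, k, k)."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    do = x.shape[1] - k + 1
    ho = x.shape[2] - k + 1
    wo = x.shape[3] - k + 1
    if min(do, ho, wo) < 1:
        raise ValueError(f"input {x.shape[1:]} too small for kernel {k}")
    y = np.empty((co, do, ho, wo), dtype=x.dtype)
    y[:] = b[:, None, None, None]
    for i in range(k):
        for j in range(k):
            for l in range(k):
                y += np.tensordot(w[:, :, i, j, l], x[:, i:i + do, j:j + ho, l:l + wo],
                                  axes=(1, 0))
    return y


def conv3d_backward(x, w, dy):
    """Gradients of conv3d. Returns (dx, dw, db)."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    do, ho, wo = dy.shape[1:]
    dx = np.zeros_like(x)
    dw = np.empty_like(w)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                dx[:, i:i + do, j:j + ho, l:l + wo] += np.tensordot(
                    w[:, :, i, j, l], dy, axes=(0, 0))
                dw[:, :, i, j, l] = np.tensordot(
                    dy, x[:, i:i + do, j:j + ho, l:l + wo], axes=([1, 2, 3], [1, 2, 3]))
    db = dy.sum(axis=(1, 2, 3))
    return dx, dw, db


def maxpool2(x):
    """2x2x2 max pooling, stride 2. Sides must be even. Returns (y, argmax)."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"odd side entering pooling: {x.shape[1:]}")
    xr = (x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
           .transpose(0, 1, 3, 5, 2, 4, 6)
           .reshape(c, d // 2, h // 2, w // 2, 8))
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(dy, idx, in_shape):
    c, d, h, w = in_shape
    g = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
    np.put_along_axis(g, idx[..., None], dy[..., None], axis=-1)
    return (g.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
             .transpose(0, 1, 4, 2, 5, 3, 6)
             .reshape(c, d, h, w))


def upconv2(x, w, b):
    """Transposed convolution, kernel 2, stride 2. w: (Cin, Cout, 2, 2, 2).

    Output side = 2 * input side; every output voxel depends on exactly one
    input voxel, so the layer doubles resolution without mixing neighbours.
    """
    ci, co = w.shape[0], w.shape[1]
    d, h, wd = x.shape[1:]
    y = np.empty((co, 2 * d, 2 * h, 2 * wd), dtype=x.dtype)
    for i in range(2):
        for j in range(2):
            for l in range(2):
                y[:, i::2, j::2, l::2] = np.tensordot(w[:, :, i, j, l], x, axes=(0, 0))
    y += b[:, None, None, None]
    return y


def upconv2_backward(x, w, dy):
    ci, co = w.shape[0], w.shape[1]
    dx = np.zeros_like(x)
    dw = np.empty_like(w)
    for i in range(2):
        for j in range(2):
            for l in range(2):
                block = dy[:, i::2, j::2, l::2]
                dx += np.tensordot(w[:, :, i, j, l], block, axes=(1, 0))
                dw[:, :, i, j, l] = np.tensordot(x, block, axes=([1, 2, 3], [1, 2, 3]))
    db = dy.sum(axis=(1, 2, 3))
    return dx, dw, db


def relu(x):
    return np.maximum(x, 0)


def relu_backward(dy, y):
    # y is the post-activation value; gradient is zero where the unit is off.
    return dy * (y > 0)


def center_crop(x, target_side: int):
    """Crop the spatial axes of (C, s, s, s) symmetrically to target_side."""
    s = x.shape[1]
    m = (s - target_side) // 2
    if m < 0 or 2 * m != s - target_side:
        raise ValueError(f"cannot center-crop side {s} to {target_side}")
    if m == 0:
        return x
    return x[:, m:s - m, m:s - m, m:s - m]


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= (lr / c1) * m / (np.sqrt(v / c2) + self.eps)
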