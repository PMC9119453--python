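"""Spatial operations (convolution, pooling, upsampling) for the autograd engine.

Convolution is evaluated as a sum over the k*k kernel offsets, each offset a
single `tensordot` over channels — memory-light and fast enough at the image
sizes this package trains on (crops of 64–256 px).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = ["conv2d", "max_pool2d", "upsample_bilinear2x", "global_avg_pool"]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout.

    x: (N, C, H, W); weight: (O, C, kh, kw); bias: (O,) or None.
    """
    x = as_tensor(x)
    weight = as_tensor(weight)
    n, c, h, w = x.shape
    o, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError("kernel larger than padded input")

    out = np.zeros((n, o, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
            # (N,C,ho,wo) x (O,C) -> (N,ho,wo,O)
            out += np.tensordot(patch, weight.data[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    if bias is not None:
        out += bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bw(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
                # dW[o,c] = sum_{n,y,x} g[n,o,y,x] * patch[n,c,y,x]
                dw[:, :, i, j] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
                # dpatch[n,c] = sum_o g[n,o] * w[o,c]
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    np.tensordot(g, weight.data[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        dx = dxp[:, :, padding:padding + h, padding:padding + w] if padding else dxp
        grads = [dx, dw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Requires even spatial dims."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        d = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(d, idx[..., None], g[..., None], axis=-1)
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (d.reshape(n, c, h, w),)

    return Tensor._make(out, (x,), bw)


@lru_cache(maxsize=32)
def _bilinear_matrix(n_in: int) -> np.ndarray:
    """(2n x n) interpolation matrix doubling a length-n axis.

    Output sample i sits at source coordinate (i + 0.5)/2 - 0.5, clipped to the
    valid range (edge replication), then linearly blended between its two
    neighbouring input samples.
    """
    n_out = 2 * n_in
    src = np.clip((np.arange(n_out) + 0.5) / 2.0 - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    m = np.zeros((n_out, n_in))
    m[np.arange(n_out), i0] += 1.0 - w1
    m[np.arange(n_out), i1] += w1
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double both spatial dimensions by bilinear interpolation."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    mr = _bilinear_matrix(h).astype(x.data.dtype)
    mc = _bilinear_matrix(w).astype(x.data.dtype)
    out = np.einsum("ij,ncjw->nciw", mr, x.data)
    out = np.einsum("kj,ncij->ncik", mc, out)

    def bw(g):
        d = np.einsum("kj,ncik->ncij", mc, g)
        d = np.einsum("ij,nciw->ncjw", mr, d)
        return (d,)

    return Tensor._make(out, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1: (N,C,H,W) -> (N,C,1,1)."""
    return as_tensor(x).mean(axis=(2, 3), keepdims=True)
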