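"""Convolution, pooling and resampling primitives (NCHW layout).

Convolutions use "same" padding in the TensorFlow sense: for kernel k and
stride s the output is ceil(H/s), with the extra padding row/column placed
at the bottom/right.  Transposed convolutions force the output size to be
exactly ``stride *`` the input size, so encoder/decoder pairings never
suffer off-by-one drift.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, _make, as_tensor


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    lo = total // 2
    return out, lo, total - lo


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            pt: int, pb: int, pl: int, pr: int) -> np.ndarray:
    """Return windows of shape (N, C, OH, OW, kh, kw)."""
    if pt or pb or pl or pr:
        x = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def _col2im(cols: np.ndarray, H: int, W: int, sh: int, sw: int,
            pt: int, pb: int, pl: int, pr: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`.  cols: (N, C, kh, kw, OH, OW)."""
    N, C, kh, kw, OH, OW = cols.shape
    out = np.zeros((N, C, H + pt + pb, W + pl + pr), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * OH:sh, j:j + sw * OW:sw] += cols[:, :, i, j]
    return out[:, :, pt:pt + H, pl:pl + W]


def conv2d(x, w, b=None, stride: int = 1) -> Tensor:
    """Same-padding 2-D convolution. w: (Cout, Cin, kh, kw), b: (Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cin}")
    OH, pt, pb = _same_pad(H, kh, stride)
    OW, pl, pr = _same_pad(W, kw, stride)
    cols = _im2col(x.data, kh, kw, stride, stride, pt, pb, pl, pr)
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * OH * OW, C * kh * kw)
    wr = w.data.reshape(Cout, C * kh * kw)
    out = cols2 @ wr.T
    if b is not None:
        out += as_tensor(b).data
    out = out.reshape(N, OH, OW, Cout).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def bwd(g):
        gr = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * OH * OW, Cout)
        dw = (gr.T @ cols2).reshape(w.data.shape)
        dcols = (gr @ wr).reshape(N, OH, OW, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
        dx = _col2im(np.ascontiguousarray(dcols), H, W, stride, stride, pt, pb, pl, pr)
        if b is None:
            return dx, dw
        return dx, dw, gr.sum(axis=0)

    return _make(out, parents, bwd)


def conv_transpose2d(x, w, b=None, stride: int = 2,
                     out_hw: tuple[int, int] | None = None) -> Tensor:
    """Transposed convolution. w: (Cin, Cout, kh, kw).

    Output spatial size defaults to ``stride * input`` (cropping/zero
    output-padding applied as needed for any kernel size).
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.data.shape
    Cin, Cout, kh, kw = w.data.shape
    if Cin != C:
        raise ValueError(f"conv_transpose2d: input has {C} channels, weight expects {Cin}")
    OH, OW = out_hw if out_hw is not None else (H * stride, W * stride)
    bufH, bufW = (H - 1) * stride + kh, (W - 1) * stride + kw
    ph, pw = max((kh - stride + 1) // 2, 0), max((kw - stride + 1) // 2, 0)
    availH, availW = min(OH, bufH - ph), min(OW, bufW - pw)
    if availH <= 0 or availW <= 0:
        raise ValueError("conv_transpose2d: requested output size incompatible with kernel")

    xr = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(N * H * W, C)
    wr = w.data.reshape(Cin, Cout * kh * kw)
    prod = (xr @ wr).reshape(N, H, W, Cout, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    buf = _col2im(np.ascontiguousarray(prod), bufH, bufW, stride, stride, 0, 0, 0, 0)
    out = np.zeros((N, Cout, OH, OW), dtype=np.float32)
    out[:, :, :availH, :availW] = buf[:, :, ph:ph + availH, pw:pw + availW]
    if b is not None:
        out += as_tensor(b).data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def bwd(g):
        gbuf = np.zeros((N, Cout, bufH, bufW), dtype=np.float32)
        gbuf[:, :, ph:ph + availH, pw:pw + availW] = g[:, :, :availH, :availW]
        win = sliding_window_view(gbuf, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        # win: (N, Cout, H, W, kh, kw)
        win2 = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * H * W, Cout * kh * kw)
        dx = (win2 @ wr.T).reshape(N, H, W, C).transpose(0, 3, 1, 2)
        dw = (xr.T @ win2).reshape(w.data.shape)
        if b is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return _make(out, parents, bwd)


def maxpool2d(x, k: int = 2) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"maxpool2d: spatial size ({H}, {W}) not divisible by {k}")
    OH, OW = H // k, W // k
    v = x.data.reshape(N, C, OH, k, OW, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, OH, OW, k * k)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dx = dv.reshape(N, C, OH, OW, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        return (dx,)

    return _make(out, (x,), bwd)


def upsample_nearest2d(x, factor: int = 2) -> Tensor:
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    out = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def bwd(g):
        return (g.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5)),)

    return _make(out, (x,), bwd)
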