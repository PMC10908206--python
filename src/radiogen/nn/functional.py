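"""Low-level 3D correlation primitives.

Everything reduces to a single strided cross-correlation implemented as
im2col + BLAS matmul.  Transposed convolution and the input-gradient of a
strided convolution are both expressed as a stride-1 correlation of a
zero-dilated tensor with a channel-swapped, spatially flipped kernel, so
only one primitive needs to be fast (and correct).

Shapes follow the (N, C, D, H, W) convention with the slice axis first.
All heavy arrays are float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# Upper bound on the number of floats materialized per im2col block.
# Keeps transient memory around ~256 MB in the worst case.
_MAX_BLOCK_ELEMS = 32 * 1024 * 1024


def out_size(n: int, k: int, s: int, p: int) -> int:
    """Output length of a valid strided correlation along one axis."""
    m = n + 2 * p - k
    if m < 0 or m % s != 0:
        raise ValueError(
            f"axis of size {n} is not compatible with kernel {k}, "
            f"stride {s}, padding {p}"
        )
    return m // s + 1


def _windows(x: np.ndarray, kernel: tuple[int, int, int],
             stride: tuple[int, int, int], pad: tuple[int, int, int]) -> np.ndarray:
    """Strided sliding-window view, (N, C, od, oh, ow, kd, kh, kw)."""
    pd, ph, pw = pad
    if pd or ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    v = sliding_window_view(x, kernel, axis=(2, 3, 4))
    sd, sh, sw = stride
    return v[:, :, ::sd, ::sh, ::sw]


def _iter_blocks(v: np.ndarray):
    """Yield contiguous im2col blocks (rows, C*k3) with their row ranges.

    ``v`` is the window view transposed to (N, od, oh, ow, C, kd, kh, kw).
    Blocks group whole batch items when small, or split along the slice
    axis for very large volumes.
    """
    n, od, oh, ow = v.shape[:4]
    ck3 = v.shape[4] * v.shape[5] * v.shape[6] * v.shape[7]
    per_item = od * oh * ow * ck3
    rows_per_item = od * oh * ow
    if per_item <= _MAX_BLOCK_ELEMS:
        group = max(1, _MAX_BLOCK_ELEMS // per_item)
        for n0 in range(0, n, group):
            n1 = min(n, n0 + group)
            block = np.ascontiguousarray(v[n0:n1]).reshape(-1, ck3)
            yield n0 * rows_per_item, n1 * rows_per_item, block
    else:
        per_slice = oh * ow * ck3
        dstep = max(1, _MAX_BLOCK_ELEMS // per_slice)
        for i in range(n):
            for d0 in range(0, od, dstep):
                d1 = min(od, d0 + dstep)
                block = np.ascontiguousarray(v[i, d0:d1]).reshape(-1, ck3)
                r0 = i * rows_per_item + d0 * oh * ow
                yield r0, r0 + (d1 - d0) * oh * ow, block


def corr3d_with_cols(x: np.ndarray, w: np.ndarray,
                     stride: tuple[int, int, int] = (1, 1, 1),
                     pad: tuple[int, int, int] = (0, 0, 0),
                     keep_cols: bool = False):
    """Strided cross-correlation of x (N,C,D,H,W) with w (O,C,kd,kh,kw).

    Returns (y, cols) where cols is the (N*out_voxels, C*k3) im2col matrix
    when ``keep_cols`` (for reuse by the weight-gradient), else None.
    """
    n, c, d, h, wd = x.shape
    o, c2, kd, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    od = out_size(d, kd, stride[0], pad[0])
    oh = out_size(h, kh, stride[1], pad[1])
    ow = out_size(wd, kw, stride[2], pad[2])
    v = _windows(x, (kd, kh, kw), stride, pad).transpose(0, 2, 3, 4, 1, 5, 6, 7)
    ck3 = c * kd * kh * kw
    wmat = w.reshape(o, -1).T
    y = np.empty((n * od * oh * ow, o), dtype=x.dtype)
    cols = np.empty((n * od * oh * ow, ck3), dtype=x.dtype) if keep_cols else None
    for r0, r1, block in _iter_blocks(v):
        np.matmul(block, wmat, out=y[r0:r1])
        if keep_cols:
            cols[r0:r1] = block
    return y.reshape(n, od, oh, ow, o).transpose(0, 4, 1, 2, 3), cols


def corr3d(x: np.ndarray, w: np.ndarray,
           stride: tuple[int, int, int] = (1, 1, 1),
           pad: tuple[int, int, int] = (0, 0, 0),
           bias: np.ndarray | None = None) -> np.ndarray:
    """Strided cross-correlation; see corr3d_with_cols."""
    y, _ = corr3d_with_cols(x, w, stride, pad, keep_cols=False)
    if bias is not None:
        y += bias.reshape(1, -1, 1, 1, 1)
    return y


def corr3d_grad_w(x: np.ndarray, gy: np.ndarray, kernel: tuple[int, int, int],
                  stride: tuple[int, int, int], pad: tuple[int, int, int]) -> np.ndarray:
    """Kernel gradient of corr3d; gy is (N,O,od,oh,ow)."""
    c = x.shape[1]
    o = gy.shape[1]
    kd, kh, kw = kernel
    v = _windows(x, kernel, stride, pad).transpose(0, 2, 3, 4, 1, 5, 6, 7)
    gyr = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
    gw = np.zeros((c * kd * kh * kw, o), dtype=x.dtype)
    for r0, r1, block in _iter_blocks(v):
        gw += block.T @ gyr[r0:r1]
    return gw.T.reshape(o, c, kd, kh, kw)


def dilate(x: np.ndarray, stride: tuple[int, int, int]) -> np.ndarray:
    """Insert stride-1 zeros between entries along each spatial axis."""
    sd, sh, sw = stride
    if sd == sh == sw == 1:
        return x
    n, c, d, h, w = x.shape
    z = np.zeros((n, c, (d - 1) * sd + 1, (h - 1) * sh + 1, (w - 1) * sw + 1),
                 dtype=x.dtype)
    z[:, :, ::sd, ::sh, ::sw] = x
    return z


def _swap_flip(w: np.ndarray) -> np.ndarray:
    """(O,C,kd,kh,kw) -> (C,O,kd,kh,kw) with spatial axes reversed."""
    return np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))


def corr3d_grad_x(gy: np.ndarray, w: np.ndarray,
                  stride: tuple[int, int, int], pad: tuple[int, int, int],
                  x_shape: tuple[int, ...]) -> np.ndarray:
    """Input gradient of corr3d, computed as a transposed correlation."""
    _, _, kd, kh, kw = w.shape
    z = dilate(gy, stride)
    gx = corr3d(z, _swap_flip(w), (1, 1, 1),
                (kd - 1 - pad[0], kh - 1 - pad[1], kw - 1 - pad[2]))
    assert gx.shape == x_shape, (gx.shape, x_shape)
    return gx


def conv_transpose3d(x: np.ndarray, w: np.ndarray,
                     stride: tuple[int, int, int] = (1, 1, 1),
                     pad: tuple[int, int, int] = (0, 0, 0),
                     bias: np.ndarray | None = None) -> np.ndarray:
    """Transposed convolution; w is (C_in, C_out, kd, kh, kw)."""
    _, _, kd, kh, kw = w.shape
    z = dilate(x, stride)
    y = corr3d(z, _swap_flip(w), (1, 1, 1),
               (kd - 1 - pad[0], kh - 1 - pad[1], kw - 1 - pad[2]))
    if bias is not None:
        y += bias.reshape(1, -1, 1, 1, 1)
    return y


def conv_transpose3d_grad(x: np.ndarray, gy: np.ndarray, w: np.ndarray,
                          stride: tuple[int, int, int],
                          pad: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(grad_x, grad_w) for conv_transpose3d."""
    _, _, kd, kh, kw = w.shape
    q = (kd - 1 - pad[0], kh - 1 - pad[1], kw - 1 - pad[2])
    # grad through the stride-1 correlation of the dilated input
    z = dilate(x, stride)
    gwf = corr3d_grad_w(z, gy, (kd, kh, kw), (1, 1, 1), q)     # (Cout,Cin,k...)
    gw = _swap_flip(gwf)                                        # back to (Cin,Cout)
    gz = corr3d_grad_x(gy, _swap_flip(w), (1, 1, 1), q, z.shape)
    sd, sh, sw = stride
    gx = np.ascontiguousarray(gz[:, :, ::sd, ::sh, ::sw])
    return gx, gw
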