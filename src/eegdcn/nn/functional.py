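"""Array-level neural-network primitives with hand-written backward passes.

Everything operates on NCHW batches. ``conv2d`` uses an im2col expansion;
``deform_conv2d`` evaluates the kernel at per-position offset sampling
points resolved by bilinear interpolation, with samples outside the map
treated as zero.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv_output_size",
    "deform_conv2d",
    "bilinear_sample",
    "channel_conv1d",
    "softmax",
    "softmax_cross_entropy",
]


def conv_output_size(n: int, p: int, f: int, s: int) -> int:
    """Spatial output size of a convolution: ``(n + 2p - f) // s + 1``."""
    if f > n + 2 * p:
        raise ValueError(f"kernel {f} larger than padded input {n + 2 * p}")
    return (n + 2 * p - f) // s + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x.shape
    Ho = conv_output_size(H, pad, kh, stride)
    Wo = conv_output_size(W, pad, kw, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride]
    return cols


def _col2im(cols: np.ndarray, x_shape, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x_shape
    _, _, kh, kw, Ho, Wo = cols.shape
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad : pad + H, pad : pad + W]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation of an NCHW batch with an OIHW kernel."""
    x, weight = as_tensor(x), as_tensor(weight)
    O, I, kh, kw = weight.data.shape
    if x.data.shape[1] != I:
        raise ValueError(f"input has {x.data.shape[1]} channels, kernel expects {I}")
    cols = _im2col(x.data, kh, kw, stride, pad)  # (B,C,kh,kw,Ho,Wo)
    B, _, _, _, Ho, Wo = cols.shape
    cols_mat = cols.reshape(B, I * kh * kw, Ho * Wo)
    w_mat = weight.data.reshape(O, I * kh * kw)
    out = (w_mat @ cols_mat).reshape(B, O, Ho, Wo)
    parents = [x, weight]
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)
        parents.append(bias)

    def backward(g):
        g_mat = g.reshape(B, O, Ho * Wo)
        if weight.requires_grad:
            dw = np.einsum("bol,bil->oi", g_mat, cols_mat).reshape(O, I, kh, kw)
            weight._accumulate(dw)
        if x.requires_grad:
            dcols = np.matmul(w_mat.T, g_mat).reshape(B, I, kh, kw, Ho, Wo)
            x._accumulate(_col2im(dcols, x.data.shape, stride, pad))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out, tuple(parents), backward)


# --------------------------------------------------------------------------
# bilinear sampling & deformable convolution
# --------------------------------------------------------------------------

def _bilinear_parts(py: np.ndarray, px: np.ndarray, H: int, W: int):
    """Corner indices, weights and validity masks for zero-padded sampling."""
    y0 = np.floor(py)
    x0 = np.floor(px)
    fy = py - y0
    fx = px - x0
    y0 = y0.astype(np.int64)
    x0 = x0.astype(np.int64)
    parts = []
    for dy, dx, wy, wx in (
        (0, 0, 1.0 - fy, 1.0 - fx),
        (0, 1, 1.0 - fy, fx),
        (1, 0, fy, 1.0 - fx),
        (1, 1, fy, fx),
    ):
        yi = y0 + dy
        xi = x0 + dx
        valid = (yi >= 0) & (yi < H) & (xi >= 0) & (xi < W)
        parts.append((np.clip(yi, 0, H - 1), np.clip(xi, 0, W - 1), wy * wx * valid, valid))
    return parts, fy, fx, y0, x0


def bilinear_sample(x: np.ndarray, q: tuple[float, float]) -> float:
    """Sample a single-channel 2D map at fractional position ``q = (row, col)``.

    Positions fully or partly outside the map draw zeros from the missing
    corners (zero-padding convention).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("bilinear_sample expects a 2D map")
    H, W = x.shape
    py = np.asarray([float(q[0])])
    px = np.asarray([float(q[1])])
    parts, *_ = _bilinear_parts(py, px, H, W)
    value = 0.0
    for yi, xi, w, _ in parts:
        value += float(w[0]) * x[yi[0], xi[0]]
    return value


def _sample_map(x: np.ndarray, py: np.ndarray, px: np.ndarray):
    """Bilinear gather: x (B,C,H,W), positions (B,Ho,Wo) -> (B,C,Ho,Wo)."""
    B, C, H, W = x.shape
    parts, fy, fx, _, _ = _bilinear_parts(py, px, H, W)
    xf = x.reshape(B, C, H * W)
    bidx = np.arange(B)[:, None, None]
    out = np.zeros((B, C) + py.shape[1:], dtype=x.dtype)
    corner_vals = []
    for yi, xi, w, valid in parts:
        v = xf[bidx, :, (yi * W + xi)]  # (B,Ho,Wo,C)
        v = np.moveaxis(v, -1, 1) * valid[:, None]
        corner_vals.append(v)
        out += v * w[:, None]
    return out, parts, corner_vals, fy, fx


def deform_conv2d(
    x: Tensor,
    offsets: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    pad: int = 1,
) -> Tensor:
    """Deformable 2D convolution.

    ``offsets`` has ``2*N`` channels for an ``N``-element kernel, laid out as
    (dy, dx) pairs per kernel element in row-major kernel order, at the output
    resolution. Each kernel tap is evaluated at its regular grid position
    displaced by its learned offset; fractional positions are resolved by
    bilinear interpolation and out-of-map samples contribute zero.
    """
    x, offsets, weight = as_tensor(x), as_tensor(offsets), as_tensor(weight)
    O, I, kh, kw = weight.data.shape
    N = kh * kw
    if offsets.data.shape[1] != 2 * N:
        raise ValueError(f"offset map must have {2 * N} channels, got {offsets.data.shape[1]}")
    B, C, H, W = x.data.shape
    if C != I:
        raise ValueError(f"input has {C} channels, kernel expects {I}")
    Ho = conv_output_size(H, pad, kh, stride)
    Wo = conv_output_size(W, pad, kw, stride)
    if offsets.data.shape[2:] != (Ho, Wo):
        raise ValueError(
            f"offset map spatial dims {offsets.data.shape[2:]} do not match output {(Ho, Wo)}"
        )

    base_y = (np.arange(Ho) * stride - pad)[None, :, None]
    base_x = (np.arange(Wo) * stride - pad)[None, None, :]

    sampled = np.empty((B, N, C, Ho, Wo), dtype=x.data.dtype)
    caches = []
    for n in range(N):
        ki, kj = divmod(n, kw)
        py = base_y + ki + offsets.data[:, 2 * n]
        px = base_x + kj + offsets.data[:, 2 * n + 1]
        vals, parts, corner_vals, fy, fx = _sample_map(x.data, py, px)
        sampled[:, n] = vals
        caches.append((py, px, parts, corner_vals, fy, fx))

    # contract sampled taps with the kernel: out[b,o] = sum_{n,c} w[o,c,n] * s[b,n,c]
    w_mat = weight.data.transpose(1, 2, 3, 0).reshape(I * N, O)  # rows ordered (c, n)
    s_mat = sampled.transpose(0, 2, 1, 3, 4).reshape(B, C * N, Ho * Wo)
    out = np.matmul(w_mat.T, s_mat).reshape(B, O, Ho, Wo)
    parents = [x, offsets, weight]
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)
        parents.append(bias)

    def backward(g):
        g_mat = g.reshape(B, O, Ho * Wo)
        if weight.requires_grad:
            dw = np.einsum("bol,bil->io", g_mat, s_mat)  # (C*N, O)
            weight._accumulate(dw.reshape(I, kh, kw, O).transpose(3, 0, 1, 2))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if not (x.requires_grad or offsets.requires_grad):
            return
        ds = np.matmul(w_mat, g_mat).reshape(B, C, N, Ho, Wo)  # grad wrt sampled values
        dx = np.zeros_like(x.data) if x.requires_grad else None
        doff = np.zeros_like(offsets.data) if offsets.requires_grad else None
        for n in range(N):
            dval = ds[:, :, n]  # (B,C,Ho,Wo)
            py, px, parts, corner_vals, fy, fx = caches[n]
            if dx is not None:
                dxf = dx.reshape(B, C, H * W)
                bidx = np.arange(B)[:, None, None, None]
                cidx = np.arange(C)[None, :, None, None]
                for yi, xi, w, valid in parts:
                    idx = (yi * W + xi)[:, None]
                    np.add.at(dxf, (bidx, cidx, idx), dval * w[:, None])
            if doff is not None:
                v00, v01, v10, v11 = corner_vals
                dv_dy = (1.0 - fx)[:, None] * (v10 - v00) + fx[:, None] * (v11 - v01)
                dv_dx = (1.0 - fy)[:, None] * (v01 - v00) + fy[:, None] * (v11 - v10)
                doff[:, 2 * n] = (dval * dv_dy).sum(axis=1)
                doff[:, 2 * n + 1] = (dval * dv_dx).sum(axis=1)
        if dx is not None:
            x._accumulate(dx)
        if doff is not None:
            offsets._accumulate(doff)

    return Tensor._from_op(out, tuple(parents), backward)


# --------------------------------------------------------------------------
# 1D convolution across the channel axis (attention gate)
# --------------------------------------------------------------------------

def channel_conv1d(x: Tensor, weight: Tensor) -> Tensor:
    """Same-size 1D convolution of each row of ``x`` (B, C) with kernel ``weight`` (k,)."""
    x, weight = as_tensor(x), as_tensor(weight)
    (k,) = weight.data.shape
    if k % 2 != 1:
        raise ValueError("channel kernel size must be odd")
    pad = k // 2
    B, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,C,k)
    out = windows @ weight.data

    def backward(g):
        if weight.requires_grad:
            weight._accumulate(np.einsum("bc,bck->k", g, windows))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (pad, pad)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
            x._accumulate(gwin @ weight.data[::-1].copy())

    return Tensor._from_op(out, (x, weight), backward)


# --------------------------------------------------------------------------
# classification head
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on a plain array (inference path)."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    B = logits.data.shape[0]
    probs = softmax(logits.data, axis=1)
    eps = np.finfo(np.float64).tiny
    loss = -np.log(probs[np.arange(B), labels] + eps).mean()

    def backward(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(B), labels] -= 1.0
            logits._accumulate(g * d / B)

    return Tensor._from_op(np.asarray(loss), (logits,), backward)
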