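"""Fused differentiable primitives: convolution, normalisation, resampling.

Convolution is implemented as a shift-multiply-accumulate over the k*k kernel
offsets: for every offset the strided input slice is contracted with the
corresponding kernel slab through one BLAS matmul. This keeps memory at one
activation-sized buffer (no im2col materialisation) and makes the backward
pass an exact mirror of the forward loop.
"""

from __future__ import annotations

import numpy as np

from . import profile
from .tensor import Tensor


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int | None = None, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout.

    ``padding=None`` means "same" padding (k // 2). ``groups`` supports the
    two cases the architecture uses — full (1) and depthwise (C) — plus a
    generic grouped fallback.
    """
    B, C, H, W = x.shape
    Cout, Cin_g, kh, kw = w.shape
    if Cin_g * groups != C:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels but kernel expects "
            f"{Cin_g * groups} (Cin/groups={Cin_g}, groups={groups})"
        )
    sh, sw = _pair(stride)
    if padding is None:
        ph, pw = kh // 2, kw // 2
    else:
        ph, pw = _pair(padding)
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(
            f"conv2d: input {H}x{W} too small for kernel {kh}x{kw} "
            f"with padding ({ph},{pw})"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) \
        if (ph or pw) else x.data

    depthwise = groups == C and Cin_g == 1 and Cout == C
    y = np.zeros((B, Cout, Ho, Wo), dtype=np.float32)
    if depthwise:
        for ki in range(kh):
            for kj in range(kw):
                patch = xp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
                y += w.data[:, 0, ki, kj][None, :, None, None] * patch
    elif groups == 1:
        for ki in range(kh):
            for kj in range(kw):
                patch = xp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
                y += (w.data[:, :, ki, kj] @ patch.reshape(B, C, -1)
                      ).reshape(B, Cout, Ho, Wo)
    else:
        cg, og = C // groups, Cout // groups
        for g in range(groups):
            wg = w.data[g * og:(g + 1) * og]
            xg = xp[:, g * cg:(g + 1) * cg]
            for ki in range(kh):
                for kj in range(kw):
                    patch = xg[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
                    y[:, g * og:(g + 1) * og] += (
                        wg[:, :, ki, kj] @ patch.reshape(B, cg, -1)
                    ).reshape(B, og, Ho, Wo)
    if b is not None:
        y += b.data[None, :, None, None]
    profile.add(B * Cout * Cin_g * kh * kw * Ho * Wo)

    parents = (x, w) if b is None else (x, w, b)

    def backward(gy):
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        dxp = np.zeros_like(xp) if need_x else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        gflat = gy.reshape(B, Cout, -1)
        if depthwise:
            for ki in range(kh):
                for kj in range(kw):
                    patch = xp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
                    if dw is not None:
                        dw[:, 0, ki, kj] = (gy * patch).sum(axis=(0, 2, 3))
                    if need_x:
                        dxp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw] += \
                            w.data[:, 0, ki, kj][None, :, None, None] * gy
        elif groups == 1:
            for ki in range(kh):
                for kj in range(kw):
                    patch = xp[:, :, ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw]
                    if dw is not None:
                        pf = patch.reshape(B, C, -1)
                        dw[:, :, ki, kj] = np.einsum(
                            "bol,bcl->oc", gflat, pf, optimize=True)
                    if need_x:
                        contrib = (w.data[:, :, ki, kj].T @ gflat
                                   ).reshape(B, C, Ho, Wo)
                        dxp[:, :, ki:ki + sh * Ho:sh,
                            kj:kj + sw * Wo:sw] += contrib
        else:
            cg, og = C // groups, Cout // groups
            for g in range(groups):
                wg = w.data[g * og:(g + 1) * og]
                xg = xp[:, g * cg:(g + 1) * cg]
                gg = gy[:, g * og:(g + 1) * og].reshape(B, og, -1)
                for ki in range(kh):
                    for kj in range(kw):
                        patch = xg[:, :, ki:ki + sh * Ho:sh,
                                   kj:kj + sw * Wo:sw]
                        if dw is not None:
                            dw[g * og:(g + 1) * og, :, ki, kj] = np.einsum(
                                "bol,bcl->oc", gg, patch.reshape(B, cg, -1),
                                optimize=True)
                        if need_x:
                            contrib = (wg[:, :, ki, kj].T @ gg
                                       ).reshape(B, cg, Ho, Wo)
                            dxp[:, g * cg:(g + 1) * cg,
                                ki:ki + sh * Ho:sh, kj:kj + sw * Wo:sw] += contrib
        if dw is not None:
            w._accum(dw)
        if need_x:
            x._accum(dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp)

    return Tensor._make(y, parents, backward)


def conv1d_depthwise(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise 1-D conv over the last axis of a (B, C, L) sequence.

    Used by the attention gates that operate on pooled axis profiles.
    """
    B, C, L = x.shape
    k = w.shape[-1]
    x4 = x.reshape(B, C, 1, L)
    w4 = w.reshape(C, 1, 1, k)
    y = conv2d(x4, w4, b, stride=1, padding=(0, k // 2), groups=C)
    return y.reshape(B, C, L)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.03,
               eps: float = 1e-3) -> Tensor:
    """Channel-wise batch normalisation (NCHW).

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used.
    """
    axes = (0, 2, 3)
    if training:
        # accumulate in float64: activations can be large early in training
        mu = x.data.mean(axis=axes, dtype=np.float64).astype(np.float32)
        var = x.data.var(axis=axes, dtype=np.float64,
                         mean=mu[None, :, None, None]).astype(np.float32)
        n = x.data.size / x.shape[1]
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gy):
        if gamma.requires_grad:
            gamma._accum((gy * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(gy.sum(axis=axes))
        if x.requires_grad:
            h = gy * gamma.data[None, :, None, None]
            if training:
                m = x.data.size / x.shape[1]
                dx = (h - h.mean(axis=axes, keepdims=True)
                      - xhat * (h * xhat).mean(axis=axes, keepdims=True)
                      ) / std[None, :, None, None]
            else:
                dx = h / std[None, :, None, None]
            x._accum(dx)

    return Tensor._make(y, (x, gamma, beta), backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalisation over (C/groups, *spatial) per sample.

    Accepts (B, C, ...) input of any spatial rank; a constant input maps to
    exactly zero, which the attention gates rely on.
    """
    shape = x.shape
    B, C = shape[0], shape[1]
    if C % groups:
        raise ValueError(f"group_norm: {C} channels not divisible by {groups} groups")
    xg = x.data.reshape(B, groups, -1)
    mu = xg.mean(axis=2, keepdims=True, dtype=np.float64).astype(np.float32)
    var = xg.var(axis=2, keepdims=True, dtype=np.float64,
                 mean=mu).astype(np.float32)
    std = np.sqrt(var + eps)
    xhat = ((xg - mu) / std).reshape(shape)
    bshape = (1, C) + (1,) * (len(shape) - 2)
    y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

    def backward(gy):
        red = (0,) + tuple(range(2, len(shape)))
        if gamma.requires_grad:
            gamma._accum((gy * xhat).sum(axis=red))
        if beta.requires_grad:
            beta._accum(gy.sum(axis=red))
        if x.requires_grad:
            h = (gy * gamma.data.reshape(bshape)).reshape(B, groups, -1)
            xh = xhat.reshape(B, groups, -1)
            dx = (h - h.mean(axis=2, keepdims=True)
                  - xh * (h * xh).mean(axis=2, keepdims=True)) / std
            x._accum(dx.reshape(shape))

    return Tensor._make(y, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# softmax / losses
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(gy):
        if x.requires_grad:
            x._accum(out * (gy - (gy * out).sum(axis=axis, keepdims=True)))

    return Tensor._make(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def backward(gy):
        if x.requires_grad:
            x._accum(gy - sm * gy.sum(axis=axis, keepdims=True))

    return Tensor._make(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    z, t = logits.data, np.asarray(targets, dtype=np.float32)
    out = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(gy):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
            logits._accum(gy * (sig - t))

    return Tensor._make(out, (logits,), backward)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    B, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3)

    def backward(gy):
        if x.requires_grad:
            x._accum(gy.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def pixel_shuffle(x: Tensor, scale: int) -> Tensor:
    """Channel-to-space rearrangement: (B, C*s*s, H, W) -> (B, C, sH, sW).

    Output pixel (s*i + di, s*j + dj) of channel c reads input channel
    ``c*s*s + di*s + dj`` at (i, j).
    """
    B, Cs, H, W = x.shape
    s = scale
    C = Cs // (s * s)
    if C * s * s != Cs:
        raise ValueError(f"pixel_shuffle: {Cs} channels not divisible by {s * s}")
    t = x.reshape(B, C, s, s, H, W)
    t = t.transpose(0, 1, 4, 2, 5, 3)  # B C H s W s
    return t.reshape(B, C, H * s, W * s)


def grid_sample_bilinear(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear resampling of ``x`` (B,C,H,W) at ``coords`` (B,Ho,Wo,2).

    ``coords[..., 0]`` is the row (y) and ``coords[..., 1]`` the column (x)
    position in source-pixel units. Positions outside the image are clamped
    to the border, so a constant field stays constant under any offsets.
    Differentiable in both the source values and the sampling positions.
    """
    B, C, H, W = x.shape
    cy = np.clip(coords.data[..., 0], 0.0, H - 1)
    cx = np.clip(coords.data[..., 1], 0.0, W - 1)
    y0 = np.floor(cy).astype(np.int64)
    x0 = np.floor(cx).astype(np.int64)
    y0 = np.minimum(y0, H - 2) if H > 1 else np.zeros_like(y0)
    x0 = np.minimum(x0, W - 2) if W > 1 else np.zeros_like(x0)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    fy = (cy - y0)[:, None]  # B,1,Ho,Wo broadcast over channels
    fx = (cx - x0)[:, None]
    bidx = np.arange(B)[:, None, None]
    v00 = x.data[bidx, :, y0, x0].transpose(0, 3, 1, 2)
    v01 = x.data[bidx, :, y0, x1].transpose(0, 3, 1, 2)
    v10 = x.data[bidx, :, y1, x0].transpose(0, 3, 1, 2)
    v11 = x.data[bidx, :, y1, x1].transpose(0, 3, 1, 2)
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    out = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11

    def backward(gy):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for ys, xs, wgt in ((y0, x0, w00), (y0, x1, w01),
                                (y1, x0, w10), (y1, x1, w11)):
                contrib = (gy * wgt).transpose(0, 2, 3, 1)  # B,Ho,Wo,C
                np.add.at(dx, (bidx, slice(None), ys, xs), contrib)
            x._accum(dx)
        if coords.requires_grad:
            # d(out)/d(fy) summed over channels; clamped coords get zero grad
            dfy = ((v10 - v00) * (1 - fx) + (v11 - v01) * fx)
            dfx = ((v01 - v00) * (1 - fy) + (v11 - v10) * fy)
            gy_y = (gy * dfy).sum(axis=1)
            gy_x = (gy * dfx).sum(axis=1)
            my = (coords.data[..., 0] > 0) & (coords.data[..., 0] < H - 1)
            mx = (coords.data[..., 1] > 0) & (coords.data[..., 1] < W - 1)
            dc = np.stack([gy_y * my, gy_x * mx], axis=-1)
            coords._accum(dc)

    return Tensor._make(out, (x, coords), backward)


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    """Adaptive average pooling to an ``out_size`` x ``out_size`` map."""
    B, C, H, W = x.shape
    o = out_size
    if o == 1:
        return x.mean(axis=(2, 3), keepdims=True)
    hb = [(i * H // o, -(-(i + 1) * H // o)) for i in range(o)]
    wb = [(j * W // o, -(-(j + 1) * W // o)) for j in range(o)]
    out = np.empty((B, C, o, o), dtype=np.float32)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(gy):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i, (h0, h1) in enumerate(hb):
                for j, (w0, w1) in enumerate(wb):
                    area = (h1 - h0) * (w1 - w0)
                    dx[:, :, h0:h1, w0:w1] += \
                        gy[:, :, i:i + 1, j:j + 1] / area
            x._accum(dx)

    return Tensor._make(out, (x,), backward)
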