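"""Spatial-channel synergistic attention and the fusion blocks built on it.

SCSA runs two parallel pathways over a feature map X (B,C,H,W):

* **Spatial path** — the map is average-pooled along each spatial axis to
  height/width profiles, filtered by shared multi-scale depthwise 1-D
  convolutions (kernels 3/5/7), group-normalised and squashed by a sigmoid.
  The two axis gates are averaged into a spatial weight field W_s in (0,1)
  and the path emits X_s = X (x) W_s. Group normalisation maps any constant
  field to zero, so a constant input collapses to W_s = 1/2 exactly.

* **Channel path** — single-head channel self-attention. Queries come from
  the group-normalised map, keys from its spatially pooled version, both
  flattened over a small pooled token grid; A = softmax(Q K^T) is a CxC
  row-stochastic matrix applied to a full-resolution value projection. A
  parallel depthwise 9-tap gate over the pooled axis profiles provides a
  per-channel weight W_c in (0,1), and the path emits
  X_c = (A V) (x) W_c.

The module output is X_s + X_c. ``A2C2f_SCSA`` embeds SCSA inside each
area-attention unit of a split-transform-merge fusion block: two parallel
branches of chained units are concatenated with the stem projection, merged
by a 1x1 convolution, scaled by a learnable scalar and projected again.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import ops
from .nn.modules import Parameter
from .nn.tensor import Tensor, concat


@dataclass
class SCSASpec:
    """Configuration of one SCSA module."""

    channels: int
    spatial_kernels: tuple = (3, 5, 7)
    channel_kernel: int = 9
    norm_groups: int = 4
    pool_size: int = 7
    temperature: float | None = None  # None = no attention scaling
    literal_pooled: bool = False  # gate from the 1x1 GAP vector instead of axis profiles

    def __post_init__(self):
        if any(k % 2 == 0 for k in (*self.spatial_kernels, self.channel_kernel)):
            raise ValueError("attention gate kernels must be odd")
        if self.channels % self.norm_groups:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by the "
                f"group-norm group count ({self.norm_groups})")


class _DWConv1d(nn.Module):
    """Depthwise 1-D convolution over (B, C, L) sequences.

    Same-length output with *replicate* (edge) padding: a constant profile
    maps to a constant response, which the constant-input collapse of the
    attention gates relies on (zero padding would break it at the edges).
    """

    def __init__(self, c, k):
        super().__init__()
        from .nn import modules as _mods
        bound = float(np.sqrt(6.0 / k))
        self.weight = Parameter(_mods._rng.uniform(-bound, bound, (c, 1, 1, k)))

    def forward(self, x):
        B, C, L = x.shape
        pad = self.weight.shape[-1] // 2
        if pad:
            x = concat([x[:, :, :1]] * pad + [x] + [x[:, :, L - 1:]] * pad,
                       axis=2)
        y = ops.conv2d(x.reshape(B, C, 1, L + 2 * pad), self.weight, None,
                       stride=1, padding=0, groups=C)
        return y.reshape(B, C, L)


class SCSA(nn.Module):
    def __init__(self, spec: SCSASpec):
        super().__init__()
        self.spec = spec
        c, g = spec.channels, spec.norm_groups
        # spatial path: shared multi-scale depthwise filters on axis profiles.
        # Gate normalisation is per channel (one group per channel) so that a
        # constant input collapses to a gate of exactly 1/2.
        self.spatial_convs = nn.ModuleList(
            [_DWConv1d(c, k) for k in spec.spatial_kernels])
        self.spatial_norm = nn.GroupNorm(len(spec.spatial_kernels) * c,
                                         len(spec.spatial_kernels) * c)
        # channel path
        self.q_norm = nn.GroupNorm(g, c)
        self.kv_norm = nn.GroupNorm(g, c)
        self.k_proj = nn.Conv2d(c, c, 1, groups=c, bias=True)
        self.v_proj = nn.Conv2d(c, c, 1, groups=c, bias=True)
        self.gate_conv = _DWConv1d(c, spec.channel_kernel)
        self.gate_norm = nn.GroupNorm(c, c)

    # -- helpers ----------------------------------------------------------
    def _axis_profiles(self, x: Tensor):
        """Mean profiles along H and W; the literal variant uses the GAP vector."""
        if self.spec.literal_pooled:
            gap = x.mean(axis=(2, 3), keepdims=True)  # B,C,1,1
            p = gap.reshape(x.shape[0], x.shape[1], 1)
            return p, p
        ph = x.mean(axis=3)  # B,C,H
        pw = x.mean(axis=2)  # B,C,W
        return ph, pw

    def _axis_gate(self, profile: Tensor) -> Tensor:
        """Multi-scale depthwise filtering -> GN -> sigmoid, per axis."""
        feats = [conv(profile) for conv in self.spatial_convs]
        cat = concat(feats, axis=1)  # B, 3C, L
        gated = self.spatial_norm(cat).sigmoid()
        B, _, L = gated.shape
        c = self.spec.channels
        # average the per-scale gates back to C channels
        return gated.reshape(B, len(self.spatial_convs), c, L).mean(axis=1)

    # -- the two pathways -------------------------------------------------
    def spatial_attention(self, x: Tensor):
        if x.shape[1] != self.spec.channels:
            raise ValueError(f"SCSA configured for {self.spec.channels} "
                             f"channels, got {x.shape[1]}")
        ph, pw = self._axis_profiles(x)
        gh = self._axis_gate(ph)  # B,C,H (or B,C,1)
        gw = self._axis_gate(pw)  # B,C,W (or B,C,1)
        B, C = x.shape[:2]
        ws = (gh.reshape(B, C, gh.shape[2], 1)
              + gw.reshape(B, C, 1, gw.shape[2])) * 0.5
        return x * ws, ws

    def channel_attention(self, x: Tensor):
        spec = self.spec
        B, C, H, W = x.shape
        p = min(spec.pool_size, H, W)
        if spec.literal_pooled:
            p = 1
        q = ops.adaptive_avg_pool2d(self.q_norm(x), p).reshape(B, C, p * p)
        kv_pooled = self.kv_norm(ops.adaptive_avg_pool2d(x, p))
        k = self.k_proj(kv_pooled).reshape(B, C, p * p)
        v = self.v_proj(self.kv_norm(x)).reshape(B, C, H * W)
        scale = 1.0 if spec.temperature is None else spec.temperature
        attn = ops.softmax((q @ k.transpose(0, 2, 1)) * scale, axis=-1)
        attended = (attn @ v).reshape(B, C, H, W)
        # per-channel gate from the 9-tap depthwise branch on axis profiles
        ph, pw = self._axis_profiles(x)
        gh = self.gate_norm(self.gate_conv(ph)).sigmoid().mean(axis=2)
        gw = self.gate_norm(self.gate_conv(pw)).sigmoid().mean(axis=2)
        wc = ((gh + gw) * 0.5).reshape(B, C, 1, 1)
        return attended * wc, (attn, wc)

    def forward(self, x: Tensor) -> Tensor:
        xs, _ = self.spatial_attention(x)
        xc, _ = self.channel_attention(x)
        return xs + xc


# ---------------------------------------------------------------------------
# area attention units and the fusion blocks
# ---------------------------------------------------------------------------

class AreaAttention(nn.Module):
    """Windowed (area) multi-head self-attention over flattened tokens.

    The token sequence is split into ``area`` contiguous chunks attended
    independently; ``area=1`` is full global attention. A depthwise 7x7
    positional branch on the value projection restores spatial locality.
    """

    def __init__(self, dim, area=4, head_dim=32):
        super().__init__()
        heads = max(1, dim // head_dim)
        while dim % heads:  # snap down to a divisor of dim
            heads -= 1
        self.heads = heads
        self.dim, self.area = dim, area
        self.qk = nn.ConvBN(dim, 2 * dim, 1, act="none")
        self.v = nn.ConvBN(dim, dim, 1, act="none")
        self.pe = nn.Conv2d(dim, dim, 7, groups=dim, bias=False)
        self.proj = nn.ConvBN(dim, dim, 1, act="none")

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        N = H * W
        a = self.area if N % self.area == 0 else 1
        h = self.heads
        dh = C // h
        qk = self.qk(x)
        v = self.v(x)

        def split_heads(t):
            return (t.reshape(B, h, dh, a, N // a)
                    .transpose(0, 3, 1, 4, 2))  # B,a,h,Na,dh

        q = split_heads(qk[:, :C].reshape(B, C, N))
        k = split_heads(qk[:, C:].reshape(B, C, N))
        vv = split_heads(v.reshape(B, C, N))
        attn = ops.softmax((q @ k.transpose(0, 1, 2, 4, 3)) * (dh ** -0.5),
                           axis=-1)
        o = (attn @ vv).transpose(0, 2, 4, 1, 3).reshape(B, C, H, W)
        return self.proj(o + self.pe(v))


class ABlock(nn.Module):
    """Area-attention unit: attention and a 1x1 conv MLP, each residual."""

    def __init__(self, dim, area=4, mlp_ratio=1.2):
        super().__init__()
        self.attn = AreaAttention(dim, area)
        hidden = max(4, int(dim * mlp_ratio))
        self.mlp = nn.Sequential(nn.ConvBN(dim, hidden, 1, act="silu"),
                                 nn.ConvBN(hidden, dim, 1, act="none"))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp(x)


class ABlockSCSA(ABlock):
    """Area-attention unit with SCSA inserted between attention and MLP."""

    def __init__(self, dim, area=4, mlp_ratio=1.2, norm_groups=4,
                 **scsa_kwargs):
        super().__init__(dim, area, mlp_ratio)
        self.scsa = SCSA(SCSASpec(channels=dim, norm_groups=norm_groups,
                                  **scsa_kwargs))

    def forward(self, x):
        x = x + self.attn(x)
        x = self.scsa(x)
        return x + self.mlp(x)


class A2C2f(nn.Module):
    """Baseline area-attention fusion block (split, chain, concat, merge)."""

    def __init__(self, cin, cout, n=1, area=4, e=0.5, mlp_ratio=1.2,
                 residual=False):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = nn.ConvBN(cin, c_, 1)
        self.m = nn.ModuleList([
            nn.Sequential(ABlock(c_, area, mlp_ratio),
                          ABlock(c_, area, mlp_ratio))
            for _ in range(n)])
        self.cv2 = nn.ConvBN((1 + n) * c_, cout, 1)
        self.residual = residual and cin == cout
        if self.residual:
            self.gamma = Parameter(np.ones(1))

    def forward(self, x):
        ys = [self.cv1(x)]
        for m in self.m:
            ys.append(m(ys[-1]))
        out = self.cv2(concat(ys, axis=1))
        if self.residual:
            return x + self.gamma * out
        return out


@dataclass
class A2C2fSCSASpec:
    """Configuration of one SCSA fusion block."""

    in_channels: int
    out_channels: int
    hidden_channels: int
    block_depth: int = 2  # chained units per branch
    area: int = 4
    mlp_ratio: float = 1.2
    norm_groups: int = 4
    shared_branches: bool = False


class A2C2fSCSA(nn.Module):
    """SCSA fusion block:

        X1   = Conv(Xin)                   (1x1 stem projection)
        X2   = unit(... unit(X1))          branch A, block_depth units
        X3   = unit(... unit(X1))          branch B (independent or shared)
        Xcat = Conv(concat(X1, X2, X3))    1x1 merge
        Xout = Conv(Scaling(Xcat))         learnable scalar, 1x1 projection
    """

    def __init__(self, spec: A2C2fSCSASpec):
        super().__init__()
        self.spec = spec
        c_ = spec.hidden_channels

        def branch():
            return nn.Sequential(*[
                ABlockSCSA(c_, spec.area, spec.mlp_ratio, spec.norm_groups)
                for _ in range(spec.block_depth)])

        self.cv1 = nn.ConvBN(spec.in_channels, c_, 1)
        self.branch_a = branch()
        if not spec.shared_branches:
            self.branch_b = branch()
        # the merge conv compresses to half width; the scaled output
        # projection restores it (keeps the high-resolution sites light)
        c_mid = max(8, spec.out_channels // 2)
        self.cv2 = nn.ConvBN(3 * c_, c_mid, 1)
        self.scaling = Parameter(np.ones(1))
        self.cv3 = nn.ConvBN(c_mid, spec.out_channels, 1)

    def forward(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"fusion block expects {self.spec.in_channels} "
                             f"channels, got {x.shape[1]}")
        x1 = self.cv1(x)
        x2 = self.branch_a(x1)
        x3 = (self.branch_a if self.spec.shared_branches
              else self.branch_b)(x1)
        xcat = self.cv2(concat([x1, x2, x3], axis=1))
        return self.cv3(self.scaling * xcat)


# -- functional aliases matching the operation-level contract ---------------

def spatial_attention(x: Tensor, scsa: SCSA):
    return scsa.spatial_attention(x)


def channel_attention(x: Tensor, scsa: SCSA):
    return scsa.channel_attention(x)


def scsa_forward(x: Tensor, scsa: SCSA) -> Tensor:
    return scsa(x)


def a2c2f_scsa_forward(x: Tensor, block: A2C2fSCSA) -> Tensor:
    return block(x)
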