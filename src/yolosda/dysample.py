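"""Content-aware dynamic upsampling by learned point resampling.

Instead of interpolating on a fixed stencil, the upsampler resamples the
source feature map at learned, content-dependent positions. Two linear
(1x1) branches predict per-output-pixel offsets in source-pixel units:

* a *static* branch — ``PixelShuffle(Linear1(X))`` scaled by a fixed range
  factor (0.25) — perturbs the uniform base grid, and
* a *dynamic* branch — ``PixelShuffle(0.5 * sigmoid(Linear2(X)) * Linear3(X))``
  — modulates the offset magnitude by the local content through a sigmoid
  gate.

The summed offsets displace a half-pixel-aligned base grid G (output pixel
(i, j) maps to source position ((i + 0.5)/s - 0.5)), and the feature map is
bilinearly resampled at G + O with border clamping. With both branches
zeroed the operator reduces exactly to bilinear x s upsampling. Offsets are
predicted per *group* of channels (g groups share one (dy, dx) pair per
output pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import ops
from .nn.tensor import Tensor, concat


@dataclass
class DySampleSpec:
    """Configuration of one dynamic upsampling site."""

    in_channels: int
    scale: int = 2
    groups: int = 4
    static_range: float = 0.25
    dynamic_gate: float = 0.5

    def __post_init__(self):
        if self.scale < 2:
            raise ValueError("upsampling scale must be >= 2")
        if self.groups < 1 or self.in_channels % self.groups:
            raise ValueError(
                f"channels ({self.in_channels}) must be divisible by the "
                f"offset group count ({self.groups})")

    @property
    def offset_channels(self) -> int:
        return 2 * self.groups * self.scale ** 2


class DySample(nn.Module):
    def __init__(self, spec: DySampleSpec):
        super().__init__()
        self.spec = spec
        oc = spec.offset_channels
        self.lin_static = nn.Conv2d(spec.in_channels, oc, 1, bias=True)
        self.lin_gate = nn.Conv2d(spec.in_channels, oc, 1, bias=True)
        self.lin_dyn = nn.Conv2d(spec.in_channels, oc, 1, bias=True)

    def _check(self, x):
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"dynamic upsampler configured for {self.spec.in_channels} "
                f"channels, got {x.shape[1]}")

    def static_offsets(self, x: Tensor) -> Tensor:
        """Baseline offsets (B, sH, sW, 2g), an affine function of x."""
        self._check(x)
        o = ops.pixel_shuffle(self.lin_static(x), self.spec.scale)
        o = o * self.spec.static_range
        return o.transpose(0, 2, 3, 1)

    def dynamic_offsets(self, x: Tensor) -> Tensor:
        """Sigmoid-gated offsets; |value| <= gate * |Linear3 response| / 2."""
        self._check(x)
        scaled = (self.lin_gate(x).sigmoid() * self.lin_dyn(x)
                  * self.spec.dynamic_gate)
        o = ops.pixel_shuffle(scaled, self.spec.scale)
        return o.transpose(0, 2, 3, 1)

    def base_grid(self, H: int, W: int) -> np.ndarray:
        """Uniform bilinear source grid (sH, sW, 2) in source-pixel units."""
        s = self.spec.scale
        ys = (np.arange(s * H, dtype=np.float32) + 0.5) / s - 0.5
        xs = (np.arange(s * W, dtype=np.float32) + 0.5) / s - 0.5
        return np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        self._check(x)
        B, C, H, W = x.shape
        spec = self.spec
        offsets = self.static_offsets(x) + self.dynamic_offsets(x)
        grid = self.base_grid(H, W)[None]  # 1,sH,sW,2
        cg = C // spec.groups
        outs = []
        for gidx in range(spec.groups):
            coords = grid + offsets[..., 2 * gidx:2 * gidx + 2]
            outs.append(ops.grid_sample_bilinear(
                x[:, gidx * cg:(gidx + 1) * cg], coords))
        return concat(outs, axis=1)


# -- functional aliases matching the operation-level contract ---------------

def static_offsets(x: Tensor, mod: DySample) -> Tensor:
    return mod.static_offsets(x)


def dynamic_offsets(x: Tensor, mod: DySample) -> Tensor:
    return mod.dynamic_offsets(x)


def dysample_forward(x: Tensor, mod: DySample) -> Tensor:
    return mod(x)
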