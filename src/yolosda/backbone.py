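"""Star-operation backbone: a four-stage hierarchical feature extractor.

The backbone replaces a conventional detector backbone with *star blocks*:
two parallel linear branches — a 7x7 depthwise convolution capturing local
spatial structure and a 1x1 pointwise convolution mixing channels — merged
by element-wise multiplication and added back to the input:

    X_dw   = W_dw (*dw) X
    X_fc   = W_fc (*) X + b_fc
    X_star = (X_dw (x) X_fc) + X

The product of two linear maps gives implicit high-order feature
interactions at the cost of two cheap convolutions, which is what makes the
backbone light. A stride-2 stem and one stride-2 downsampling convolution
per stage yield feature strides 4/8/16/32; detection consumes the stage-2/3/4
outputs (strides 8/16/32). The global-average-pooled classification head of
the original design is intentionally omitted — a detector exports the
pyramid instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .nn.tensor import Tensor


@dataclass
class BackboneSpec:
    """Four-stage star backbone configuration.

    stage_widths/stage_depths give the channel count and star-block count of
    each stage; ``pyramid_levels`` selects which stage outputs are exported
    (stage i sits at stride ``2**(i+1)``).
    """

    stem_channels: int = 24
    stage_widths: tuple = (24, 48, 96, 192)
    stage_depths: tuple = (1, 2, 8, 3)
    pyramid_levels: tuple = (2, 3, 4)
    act: str = "relu6"

    def __post_init__(self):
        if len(self.stage_widths) != 4 or len(self.stage_depths) != 4:
            raise ValueError("star backbone is a four-stage hierarchy: "
                             "need 4 widths and 4 depths")
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if not set(self.pyramid_levels) <= {1, 2, 3, 4}:
            raise ValueError("pyramid levels must be a subset of {1,2,3,4}")


class Stem(nn.Module):
    """3x3 stride-2 convolution + BN + rectifier on the RGB input."""

    def __init__(self, cout: int, act: str = "relu6"):
        super().__init__()
        self.block = nn.ConvBN(3, cout, 3, stride=2, act=act)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 3:
            raise ValueError(
                f"stem expects a 3-channel image, got {x.shape[1]} channels "
                f"(input shape {x.shape})")
        return self.block(x)


class Downsample(nn.Module):
    """3x3 stride-2 convolution + BN + rectifier opening each stage."""

    def __init__(self, cin: int, cout: int, act: str = "relu6"):
        super().__init__()
        self.block = nn.ConvBN(cin, cout, 3, stride=2, act=act)
        self.cin = cin

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"downsample expects {self.cin} channels, "
                             f"got {x.shape[1]}")
        return self.block(x)


class StarBlock(nn.Module):
    """Depthwise-7x7 x pointwise-1x1 star operation with a residual.

    Shape preserving; with the pointwise branch zeroed the block is exactly
    the identity map. The block's rectifier (ReLU6 by default) acts on the
    merged product: the product of two linear maps grows quadratically in
    the input scale, and chaining unbounded blocks makes activations explode
    during training, so each block's residual increment is clamped. sigma(0)
    = 0 for both rectifiers, which preserves the zero-branch identity.
    """

    def __init__(self, channels: int, act: str = "relu6"):
        super().__init__()
        self.dw = nn.Conv2d(channels, channels, 7, groups=channels, bias=False)
        self.fc = nn.Conv2d(channels, channels, 1, bias=True)
        self.channels = channels
        if act not in ("relu6", "relu", "none"):
            raise ValueError(f"unsupported star-block activation {act!r}")
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"star block expects {self.channels} channels, "
                             f"got {x.shape[1]}")
        mul = self.dw(x) * self.fc(x)
        if self.act == "relu6":
            mul = mul.relu6()
        elif self.act == "relu":
            mul = mul.relu()
        return mul + x


class StarNet(nn.Module):
    """The assembled four-stage backbone emitting a feature pyramid."""

    def __init__(self, spec: BackboneSpec | None = None):
        super().__init__()
        self.spec = spec or BackboneSpec()
        s = self.spec
        self.stem = Stem(s.stem_channels, s.act)
        cin = s.stem_channels
        stages = []
        for w, d in zip(s.stage_widths, s.stage_depths):
            blocks = [Downsample(cin, w, s.act)]
            blocks += [StarBlock(w, s.act if s.act in ("relu6", "relu")
                                 else "none") for _ in range(d)]
            stages.append(nn.Sequential(*blocks))
            cin = w
        self.stages = nn.ModuleList(stages)

    @property
    def out_channels(self) -> tuple:
        return tuple(self.spec.stage_widths[lv - 1]
                     for lv in self.spec.pyramid_levels)

    def forward(self, x: Tensor) -> list:
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(
                f"backbone input must be divisible by 32, got {H}x{W}")
        y = self.stem(x)
        outs = []
        for i, stage in enumerate(self.stages, start=1):
            y = stage(y)
            if i in self.spec.pyramid_levels:
                outs.append(y)
        return outs


# -- functional aliases matching the operation-level contract ---------------

def stem_forward(x: Tensor, stem: Stem) -> Tensor:
    return stem(x)


def downsample_forward(x: Tensor, down: Downsample) -> Tensor:
    return down(x)


def star_block_forward(x: Tensor, block: StarBlock) -> Tensor:
    return block(x)


def backbone_forward(x: Tensor, net: StarNet) -> list:
    return net(x)
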