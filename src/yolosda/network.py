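"""Detector assembly: backbone + neck + anchor-free heads, with ablation
variants, box decoding, and parameter/FLOP accounting.

The skeleton is a standard one-shot detector: a feature pyramid at strides
8/16/32, a top-down path (two upsample + concat + fusion stages), a
bottom-up path (two stride-2 conv + concat + fusion stages) and three
decoupled detect heads with distribution-focal box regression. Three
independent switches select the studied variants:

* ``backbone``      — ``baseline_conv`` (conv/CSP/area-attention stack) or
                      ``starnet`` (the star-operation backbone);
* ``upsampler``     — ``nearest`` or ``dysample`` at both neck upsample sites;
* ``fusion_block``  — ``a2c2f`` or ``a2c2f_scsa`` at every fusion site.

The (starnet, dysample, a2c2f_scsa) triple is the full lightweight model.
Channel widths below are the nano-scale calibration: the baseline triple
(baseline_conv, nearest, a2c2f) is sized to 2.5 M parameters / 6.5 GFLOPs
at 640x640 and the ablation variants inherit the same rule set.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .backbone import BackboneSpec, StarNet
from .blocks import C3k2
from .dysample import DySample, DySampleSpec
from .nn import ops, profile
from .nn.tensor import Tensor, concat, no_grad
from .scsa import A2C2f, A2C2fSCSA, A2C2fSCSASpec

STRIDES = (8, 16, 32)
REG_MAX = 16


# ---------------------------------------------------------------------------
# architecture configuration
# ---------------------------------------------------------------------------

@dataclass
class ArchConfig:
    """Nano-scale width/depth calibration shared by all variants.

    ``scsa_hidden_ratio`` is the hidden-width ratio of the SCSA fusion block
    (the synergistic gates let its branches run narrower than the baseline
    block's 0.5); ``scsa_p5`` optionally deepens/widens the stride-32 site,
    where extra capacity is cheap in FLOPs.
    """

    # baseline conv backbone: stem/stage widths
    base_channels: tuple = (20, 40, 64, 64, 128, 128, 128, 256, 256)
    base_c3k2_e: float = 0.25
    # star backbone
    star_stem: int = 24
    star_widths: tuple = (24, 56, 96, 160)
    star_depths: tuple = (2, 2, 6, 2)
    # neck / head widths
    neck_p4: int = 128
    neck_p3: int = 64
    neck_p4b: int = 128
    neck_p5: int = 256
    # fusion blocks
    a2c2f_e: float = 0.5
    mlp_ratio: float = 1.2
    scsa_hidden_ratio: float = 0.0625
    scsa_depth: int = 2
    scsa_p5_hidden: int = 164
    scsa_p5_depth: int = 2
    # upsampler
    dysample_groups: int = 8


@dataclass
class ModelSpec:
    """Buildable detector variant."""

    backbone: str = "starnet"
    upsampler: str = "dysample"
    fusion_block: str = "a2c2f_scsa"
    num_classes: int = 6
    input_size: int = 640
    width_mult: float = 1.0
    arch: ArchConfig = field(default_factory=ArchConfig)

    def __post_init__(self):
        if self.backbone not in ("baseline_conv", "starnet"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.upsampler not in ("nearest", "dysample"):
            raise ValueError(f"unknown upsampler {self.upsampler!r}")
        if self.fusion_block not in ("a2c2f", "a2c2f_scsa"):
            raise ValueError(f"unknown fusion block {self.fusion_block!r}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if isinstance(self.arch, dict):
            self.arch = ArchConfig(**self.arch)

    def scaled(self, c: int) -> int:
        """Apply the width multiplier, keeping widths divisible by 4."""
        return max(8, int(round(c * self.width_mult / 4)) * 4)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["arch"] = ArchConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in d["arch"].items()})
        return cls(**d)


def yolo_sda_spec(**kw) -> ModelSpec:
    return ModelSpec(backbone="starnet", upsampler="dysample",
                     fusion_block="a2c2f_scsa", **kw)


def baseline_spec(**kw) -> ModelSpec:
    return ModelSpec(backbone="baseline_conv", upsampler="nearest",
                     fusion_block="a2c2f", **kw)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class NearestUp(nn.Module):
    def forward(self, x):
        return ops.upsample_nearest(x, 2)


class BaselineBackbone(nn.Module):
    """Conv/CSP stack with area-attention tail blocks (strides 8/16/32)."""

    def __init__(self, spec: ModelSpec, fuse):
        super().__init__()
        a = spec.arch
        c = [spec.scaled(x) for x in a.base_channels]
        e = a.base_c3k2_e
        self.l0 = nn.ConvBN(3, c[0], 3, 2)
        self.l1 = nn.ConvBN(c[0], c[1], 3, 2)
        self.l2 = C3k2(c[1], c[2], n=1, e=e)
        self.l3 = nn.ConvBN(c[2], c[3], 3, 2)
        self.l4 = C3k2(c[3], c[4], n=1, e=e)
        self.l5 = nn.ConvBN(c[4], c[5], 3, 2)
        self.l6 = fuse(c[5], c[6], n=2, area=4, residual=True, site="bb_p4")
        self.l7 = nn.ConvBN(c[6], c[7], 3, 2)
        self.l8 = fuse(c[7], c[8], n=2, area=1, residual=True, site="bb_p5")
        self.out_channels = (c[4], c[6], c[8])

    def forward(self, x):
        H, W = x.shape[-2:]
        if H % 32 or W % 32:
            raise ValueError(
                f"backbone input must be divisible by 32, got {H}x{W}")
        y = self.l1(self.l0(x))
        p3 = self.l4(self.l3(self.l2(y)))
        p4 = self.l6(self.l5(p3))
        p5 = self.l8(self.l7(p4))
        return [p3, p4, p5]


class Detect(nn.Module):
    """Decoupled anchor-free head: DFL box branch + depthwise class branch."""

    def __init__(self, nc: int, ch: tuple, reg_max: int = REG_MAX):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(nc, 100))
        boxes, clss = [], []
        for c in ch:
            boxes.append(nn.Sequential(
                nn.ConvBN(c, c2, 3), nn.ConvBN(c2, c2, 3),
                nn.Conv2d(c2, 4 * reg_max, 1, bias=True)))
            clss.append(nn.Sequential(
                nn.ConvBN(c, c, 3, groups=c), nn.ConvBN(c, c3, 1),
                nn.ConvBN(c3, c3, 3, groups=c3), nn.ConvBN(c3, c3, 1),
                nn.Conv2d(c3, nc, 1, bias=True)))
            # start with low objectness so early training is stable
            clss[-1]._seq[-1].bias.data[:] = -4.6
        self.box_heads = nn.ModuleList(boxes)
        self.cls_heads = nn.ModuleList(clss)

    def forward(self, feats):
        out = []
        for f, bh, ch_ in zip(feats, self.box_heads, self.cls_heads):
            out.append(concat([bh(f), ch_(f)], axis=1))
        return out


class Model(nn.Module):
    """Assembled detector; ``forward`` returns raw per-level head maps."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        a = spec.arch

        def fuse(cin, cout, n, area, residual=False, site=""):
            if spec.fusion_block == "a2c2f_scsa":
                if site == "bb_p5":
                    hidden = spec.scaled(a.scsa_p5_hidden)
                    depth = a.scsa_p5_depth
                else:
                    hidden = max(8, int(round(cout * a.scsa_hidden_ratio
                                              / 4)) * 4)
                    depth = a.scsa_depth
                return A2C2fSCSA(A2C2fSCSASpec(
                    in_channels=cin, out_channels=cout,
                    hidden_channels=hidden, block_depth=depth, area=area,
                    mlp_ratio=a.mlp_ratio))
            return A2C2f(cin, cout, n=n, area=area, e=a.a2c2f_e,
                         mlp_ratio=a.mlp_ratio, residual=residual)

        if spec.backbone == "starnet":
            self.backbone = StarNet(BackboneSpec(
                stem_channels=spec.scaled(a.star_stem),
                stage_widths=tuple(spec.scaled(w) for w in a.star_widths),
                stage_depths=a.star_depths))
            c3, c4, c5 = self.backbone.out_channels
        else:
            self.backbone = BaselineBackbone(spec, fuse)
            c3, c4, c5 = self.backbone.out_channels

        def make_up(c):
            if spec.upsampler == "dysample":
                return DySample(DySampleSpec(
                    in_channels=c, groups=a.dysample_groups))
            return NearestUp()

        np4, np3 = spec.scaled(a.neck_p4), spec.scaled(a.neck_p3)
        np4b, np5 = spec.scaled(a.neck_p4b), spec.scaled(a.neck_p5)
        self.up1 = make_up(c5)
        self.f1 = fuse(c5 + c4, np4, n=1, area=4, site="neck_p4")
        self.up2 = make_up(np4)
        self.f2 = fuse(np4 + c3, np3, n=1, area=4, site="neck_p3")
        self.d1 = nn.ConvBN(np3, np3, 3, 2)
        self.f3 = fuse(np3 + np4, np4b, n=1, area=4, site="neck_p4b")
        self.d2 = nn.ConvBN(np4b, np4b, 3, 2)
        self.f4 = C3k2(np4b + c5, np5, n=1, c3k=True)
        self.head_channels = (np3, np4b, np5)
        self.detect = Detect(spec.num_classes, self.head_channels)

    def forward(self, x: Tensor):
        p3, p4, p5 = self.backbone(x)
        t1 = self.f1(concat([self.up1(p5), p4], axis=1))
        n3 = self.f2(concat([self.up2(t1), p3], axis=1))
        n4 = self.f3(concat([self.d1(n3), t1], axis=1))
        n5 = self.f4(concat([self.d2(n4), p5], axis=1))
        return self.detect([n3, n4, n5])


def assemble(spec: ModelSpec, seed: int = 0) -> Model:
    """Build a variant with reproducible weight initialisation."""
    nn.seed_init(seed)
    return Model(spec)


def forward_detect(model: Model, images: Tensor):
    """Raw head outputs for a batch of (B,3,S,S) images (eval-safe)."""
    return model(images)


# ---------------------------------------------------------------------------
# decoding and non-maximum suppression
# ---------------------------------------------------------------------------

@dataclass
class Detection:
    box: tuple  # x1, y1, x2, y2 in input pixels
    score: float
    class_id: int


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def decode_raw(raw, num_classes: int, input_size: int,
               conf_threshold: float = 0.25, reg_max: int = REG_MAX):
    """Raw head maps -> per-image arrays (boxes, scores, classes)."""
    B = raw[0].shape[0]
    results = [([], [], []) for _ in range(B)]
    bins = np.arange(reg_max, dtype=np.float32)
    for level, fm in enumerate(raw):
        s = STRIDES[level]
        arr = fm.data if isinstance(fm, Tensor) else fm
        _, C, H, W = arr.shape
        box = arr[:, :4 * reg_max].reshape(B, 4, reg_max, H, W)
        e = np.exp(box - box.max(axis=2, keepdims=True))
        dist = (e / e.sum(axis=2, keepdims=True) * bins[None, None, :, None, None]
                ).sum(axis=2)  # B,4,H,W in stride units (l,t,r,b)
        cls = _sigmoid(arr[:, 4 * reg_max:])
        cy, cx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        ctr_x = (cx + 0.5) * s
        ctr_y = (cy + 0.5) * s
        x1 = ctr_x[None] - dist[:, 0] * s
        y1 = ctr_y[None] - dist[:, 1] * s
        x2 = ctr_x[None] + dist[:, 2] * s
        y2 = ctr_y[None] + dist[:, 3] * s
        score = cls.max(axis=1)
        cid = cls.argmax(axis=1)
        for b in range(B):
            keep = score[b] >= conf_threshold
            if not keep.any():
                continue
            bx = np.stack([x1[b][keep], y1[b][keep],
                           x2[b][keep], y2[b][keep]], axis=1)
            bx = np.clip(bx, 0, input_size)
            results[b][0].append(bx)
            results[b][1].append(score[b][keep])
            results[b][2].append(cid[b][keep])
    out = []
    for bx, sc, ci in results:
        if bx:
            out.append((np.concatenate(bx), np.concatenate(sc),
                        np.concatenate(ci)))
        else:
            out.append((np.zeros((0, 4)), np.zeros(0), np.zeros(0, int)))
    return out


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes, scores, classes, iou_threshold: float = 0.45):
    """Greedy per-class suppression; returns kept indices, score-sorted."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep = []
    suppressed = np.zeros(len(order), bool)
    iou = box_iou(boxes, boxes)
    for oi, i in enumerate(order):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in order[oi + 1:]:
            if (not suppressed[j] and classes[j] == classes[i]
                    and iou[i, j] > iou_threshold):
                suppressed[j] = True
    return np.array(keep, dtype=int)


def decode_and_nms(raw, num_classes: int, input_size: int,
                   conf_threshold: float = 0.25,
                   iou_threshold: float = 0.45):
    """Full post-processing; one score-descending Detection list per image."""
    if not 0 <= conf_threshold <= 1 or not 0 <= iou_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    out = []
    for boxes, scores, classes in decode_raw(raw, num_classes, input_size,
                                             conf_threshold):
        if len(scores) == 0:
            out.append([])
            continue
        keep = nms(boxes, scores, classes, iou_threshold)
        out.append([Detection(tuple(boxes[i]), float(scores[i]),
                              int(classes[i])) for i in keep])
    return out


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

@dataclass
class ComplexityReport:
    parameters: int
    flops: int  # at the declared input size, 1 MAC = 2 FLOPs
    serialized_bytes: int
    input_size: int

    @property
    def parameters_m(self) -> float:
        return round(self.parameters / 1e6, 1)

    @property
    def flops_g(self) -> float:
        return round(self.flops / 1e9, 1)

    @property
    def size_mb(self) -> float:
        return round(self.serialized_bytes / 2 ** 20, 1)

    def __str__(self):
        return (f"{self.parameters_m:.1f} M params, {self.flops_g:.1f} GFLOPs "
                f"@ {self.input_size}, {self.size_mb:.1f} MB (fp16)")


def measure(model: nn.Module, input_size: int,
            include_attention_matmuls: bool = False) -> tuple:
    """(exact parameter count, FLOPs) of a module at the given input size.

    FLOPs follow the convention detector papers print: 2 x MACs over
    convolution and linear layers. Attention matmuls can be included via the
    flag; they are excluded by default to match the reporting convention of
    the complexity tables this package reproduces.
    """
    model.eval()
    with no_grad(), profile.count_macs(include_attention_matmuls) as macs:
        model(Tensor(np.zeros((1, 3, input_size, input_size),
                              dtype=np.float32)))
    return model.num_parameters(), 2 * macs[0]


def complexity(spec: ModelSpec) -> ComplexityReport:
    model = assemble(spec)
    params, flops = measure(model, spec.input_size)
    buf = io.BytesIO()
    _write_weights(model, buf, half=True)
    return ComplexityReport(parameters=params, flops=flops,
                            serialized_bytes=buf.getbuffer().nbytes,
                            input_size=spec.input_size)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _write_weights(model: nn.Module, fobj, half: bool = False):
    sd = model.state_dict()
    if half:
        sd = {k: v.astype(np.float16) for k, v in sd.items()}
    np.savez(fobj, **sd)


def save_checkpoint(model: Model, path: str, half: bool = False):
    """Weights to ``<path>`` (npz) + ModelSpec JSON sidecar ``<path>.spec.json``."""
    with open(path, "wb") as f:
        _write_weights(model, f, half=half)
    with open(str(path) + ".spec.json", "w") as f:
        f.write(model.spec.to_json())


def load_checkpoint(path: str) -> Model:
    with open(str(path) + ".spec.json") as f:
        spec = ModelSpec.from_json(f.read())
    model = assemble(spec)
    with np.load(path) as z:
        model.load_state_dict({k: z[k].astype(np.float32) for k in z.files})
    return model
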