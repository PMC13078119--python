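"""Training and evaluation entry points.

The head is anchor-free and decoupled; training follows the conventions of
the surrounding detector ecosystem: binary cross-entropy for
classification, complete-IoU for the box geometry and a distribution-focal
term for the discretised box regression. Assignment is deliberately simple
at desk scale — each ground-truth box is assigned to the single cell
containing its centre, on the pyramid level matching its size.

All randomness (weight init, shuffling, augmentation draws) flows from the
single ``TrainConfig.seed``.
"""

from __future__ import annotations

import csv
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import evalkit
from .datakit import DatasetManifest, read_labels
from .network import (REG_MAX, STRIDES, Model, ModelSpec, decode_raw,
                      assemble, nms, save_checkpoint, yolo_sda_spec)
from .nn import ops, optim
from .nn.tensor import Tensor, no_grad, stack as tstack

LEVEL_SIZE_BOUNDS = (0.125, 0.25)  # normalized sqrt-area bounds for P3/P4
LOSS_WEIGHTS = {"box": 7.5, "cls": 0.5, "dfl": 1.5}


@dataclass
class TrainConfig:
    """Training protocol; defaults mirror the reference setup (batch 4,
    150 epochs, 640 input) and are meant to be overridden at desk scale."""

    batch_size: int = 4
    epochs: int = 150
    input_size: int = 640
    seed: int = 0
    lr0: float = 0.01
    lrf: float = 0.01            # final LR fraction (cosine decay)
    optimizer: str = "sgd"       # sgd | adam
    momentum: float = 0.9
    weight_decay: float = 5e-4
    augment: bool = True
    spec: ModelSpec = field(default_factory=yolo_sda_spec)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if isinstance(self.spec, dict):
            self.spec = ModelSpec(**self.spec)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _assign(labels, input_size, shapes):
    """Centre-cell assignment per level: (b, y, x, class, ltrb target)."""
    per_level = [[] for _ in shapes]
    for b, lbs in enumerate(labels):
        for lb in lbs:
            snorm = float(np.sqrt(lb.w * lb.h))
            lvl = 0 if snorm < LEVEL_SIZE_BOUNDS[0] else \
                1 if snorm < LEVEL_SIZE_BOUNDS[1] else 2
            H, W = shapes[lvl]
            s = STRIDES[lvl]
            gx = min(int(lb.cx * W), W - 1)
            gy = min(int(lb.cy * H), H - 1)
            cx_px, cy_px = (gx + 0.5) * s, (gy + 0.5) * s
            x1, y1, x2, y2 = lb.to_xyxy(input_size, input_size)
            ltrb = np.array([cx_px - x1, cy_px - y1, x2 - cx_px, y2 - cy_px])
            ltrb = np.clip(ltrb / s, 0.0, REG_MAX - 1 - 1e-3)
            per_level[lvl].append((b, gy, gx, lb.class_id, ltrb))
    return per_level


def _ciou(pred_xyxy: Tensor, tgt: np.ndarray) -> Tensor:
    """Complete IoU between predicted boxes (Tensor Nx4) and targets."""
    px1, py1 = pred_xyxy[:, 0], pred_xyxy[:, 1]
    px2, py2 = pred_xyxy[:, 2], pred_xyxy[:, 3]
    tx1, ty1, tx2, ty2 = tgt[:, 0], tgt[:, 1], tgt[:, 2], tgt[:, 3]
    ix1 = px1.maximum(tx1)
    iy1 = py1.maximum(ty1)
    ix2 = px2.minimum(tx2)
    iy2 = py2.minimum(ty2)
    inter = (ix2 - ix1).clip(0.0, np.inf) * (iy2 - iy1).clip(0.0, np.inf)
    pw = (px2 - px1).clip(1e-6, np.inf)
    ph = (py2 - py1).clip(1e-6, np.inf)
    tw = np.maximum(tx2 - tx1, 1e-6)
    th = np.maximum(ty2 - ty1, 1e-6)
    union = pw * ph + tw * th - inter
    iou = inter / (union + 1e-9)
    # enclosing-box diagonal and centre distance
    ex = px2.maximum(tx2) - px1.minimum(tx1)
    ey = py2.maximum(ty2) - py1.minimum(ty1)
    diag = ex * ex + ey * ey + 1e-9
    dx = (px1 + px2 - tx1 - tx2) * 0.5
    dy = (py1 + py2 - ty1 - ty2) * 0.5
    dist = (dx * dx + dy * dy) / diag
    v = (4 / np.pi ** 2) * ((ph / pw).atan() - np.arctan(th / tw)) ** 2
    alpha = v.data / (1.0 - iou.data + v.data + 1e-9)  # detached weight
    return iou - dist - v * alpha


def detection_loss(raw, labels, num_classes: int, input_size: int):
    """Composite loss; returns (Tensor scalar, dict of components)."""
    B = raw[0].shape[0]
    shapes = [fm.shape[-2:] for fm in raw]
    per_level = _assign(labels, input_size, shapes)
    n_pos = sum(len(v) for v in per_level)
    denom = max(n_pos, 1)
    box_l = cls_l = dfl_l = None

    def acc(tot, term):
        return term if tot is None else tot + term

    bins = np.arange(REG_MAX, dtype=np.float32)
    for lvl, fm in enumerate(raw):
        H, W = shapes[lvl]
        s = STRIDES[lvl]
        cls_target = np.zeros((B, num_classes, H, W), dtype=np.float32)
        assigns = per_level[lvl]
        if assigns:
            bi = np.array([a[0] for a in assigns])
            yi = np.array([a[1] for a in assigns])
            xi = np.array([a[2] for a in assigns])
            ci = np.array([a[3] for a in assigns])
            tgt_ltrb = np.stack([a[4] for a in assigns])  # n,4 stride units
            cls_target[bi, ci, yi, xi] = 1.0
            pos = fm[bi, :, yi, xi]                       # n, 4*reg+nc
            box_logits = pos[:, :4 * REG_MAX].reshape(len(assigns), 4, REG_MAX)
            dist = (ops.softmax(box_logits, axis=-1) * bins).sum(axis=-1)
            cx = (xi + 0.5) * s
            cy = (yi + 0.5) * s
            pred = tstack([cx - dist[:, 0] * s, cy - dist[:, 1] * s,
                           cx + dist[:, 2] * s, cy + dist[:, 3] * s], axis=1)
            tx1 = cx - tgt_ltrb[:, 0] * s
            ty1 = cy - tgt_ltrb[:, 1] * s
            tx2 = cx + tgt_ltrb[:, 2] * s
            ty2 = cy + tgt_ltrb[:, 3] * s
            tgt = np.stack([tx1, ty1, tx2, ty2], axis=1)
            box_l = acc(box_l, (1.0 - _ciou(pred, tgt)).sum())
            # distribution-focal: CE against the two neighbouring bins
            logp = ops.log_softmax(box_logits, axis=-1)
            il = np.floor(tgt_ltrb).astype(int)
            ir = np.minimum(il + 1, REG_MAX - 1)
            wl = (ir - tgt_ltrb).astype(np.float32)
            wr = 1.0 - wl
            ii = np.arange(len(assigns))[:, None]
            jj = np.arange(4)[None, :]
            dfl = -(logp[ii, jj, il] * wl + logp[ii, jj, ir] * wr)
            dfl_l = acc(dfl_l, dfl.sum() * 0.25)
        cls_l = acc(cls_l, ops.bce_with_logits(
            fm[:, 4 * REG_MAX:], cls_target).sum())

    zero = Tensor(np.zeros(()))
    box_l = box_l if box_l is not None else zero
    dfl_l = dfl_l if dfl_l is not None else zero
    total = (LOSS_WEIGHTS["box"] * box_l + LOSS_WEIGHTS["cls"] * cls_l
             + LOSS_WEIGHTS["dfl"] * dfl_l) * (1.0 / denom)
    parts = {"box": box_l.item() / denom, "cls": cls_l.item() / denom,
             "dfl": dfl_l.item() / denom, "n_pos": n_pos}
    return total, parts


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def _load_item(item, input_size: int):
    img = Image.open(item.image).convert("RGB")
    if img.size != (input_size, input_size):
        img = img.resize((input_size, input_size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    labels = read_labels(item.label) if os.path.exists(item.label) else []
    return arr, labels


def load_batch(items, input_size: int):
    imgs, labels = zip(*(_load_item(it, input_size) for it in items))
    return Tensor(np.stack(imgs)), list(labels)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(config: TrainConfig, manifest: DatasetManifest,
          out_dir: str | None = None, max_iters: int | None = None,
          stop_loss_fraction: float | None = None, verbose: bool = False):
    """Train a detector on a manifest; returns (model, history).

    ``history`` is a list of per-epoch dicts (epoch, loss, lr, ...).
    ``max_iters`` caps total optimisation steps; ``stop_loss_fraction``
    stops early once the running loss falls below that fraction of the
    initial loss (both used by the overfitting smoke protocol).
    """
    items = [it for it in manifest.items if it.split in ("", "train")]
    if not items:
        raise ValueError("empty training manifest")
    spec = config.spec
    model = assemble(spec, seed=config.seed)
    model.train()
    params = list(model.parameters())
    if config.optimizer == "adam":
        opt = optim.Adam(params, lr=config.lr0,
                         weight_decay=config.weight_decay)
    elif config.optimizer == "sgd":
        opt = optim.SGD(params, lr=config.lr0, momentum=config.momentum,
                        weight_decay=config.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    rng = np.random.default_rng(config.seed)
    nb = max(1, int(np.ceil(len(items) / config.batch_size)))
    total_steps = config.epochs * nb if max_iters is None \
        else min(config.epochs * nb, max_iters)
    history = []
    first_loss = None
    step = 0
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(items))
        epoch_losses = []
        t0 = time.time()
        for bi in range(nb):
            batch_items = [items[i] for i in
                           order[bi * config.batch_size:
                                 (bi + 1) * config.batch_size]]
            if not batch_items:
                continue
            x, labels = load_batch(batch_items, config.input_size)
            if config.augment:
                # photometric jitter only; boxes unchanged
                gain = rng.uniform(0.85, 1.15)
                x = Tensor(np.clip(x.data * gain, 0, 1))
            opt.zero_grad()
            raw = model(x)
            loss, parts = detection_loss(raw, labels, spec.num_classes,
                                         config.input_size)
            loss.backward()
            opt.lr = optim.cosine_lr(config.lr0, step, total_steps,
                                     config.lrf)
            opt.step()
            lval = loss.item()
            epoch_losses.append(lval)
            if first_loss is None:
                first_loss = lval
            step += 1
            if verbose and step % 10 == 0:
                print(f"epoch {epoch} step {step}: loss {lval:.3f} "
                      f"(box {parts['box']:.3f} cls {parts['cls']:.3f})")
            running = float(np.mean(epoch_losses[-10:]))
            if stop_loss_fraction is not None and \
                    running <= stop_loss_fraction * first_loss:
                done = True
            if max_iters is not None and step >= max_iters:
                done = True
            if done:
                break
        history.append({"epoch": epoch, "loss": float(np.mean(epoch_losses)),
                        "lr": opt.lr, "seconds": time.time() - t0,
                        "steps": step})
        if done:
            break

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        save_checkpoint(model, os.path.join(out_dir, "weights.npz"))
        with open(os.path.join(out_dir, "config.json"), "w") as f:
            import json
            from dataclasses import asdict
            f.write(json.dumps(asdict(config), indent=1, default=str))
        with open(os.path.join(out_dir, "history.csv"), "w", newline="") as f:
            wr = csv.DictWriter(f, fieldnames=list(history[0]))
            wr.writeheader()
            wr.writerows(history)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def predict(model: Model, items, input_size: int,
            conf_threshold: float = 0.25, iou_threshold: float = 0.45):
    """Run the detector over manifest items; per-image (boxes, scores, cls)."""
    model.eval()
    preds = []
    with no_grad():
        for it in items:
            x, _ = load_batch([it], input_size)
            raw = model(x)
            (boxes, scores, classes), = decode_raw(
                raw, model.spec.num_classes, input_size, conf_threshold)
            if len(scores):
                keep = nms(boxes, scores, classes, iou_threshold)
                boxes, scores, classes = boxes[keep], scores[keep], classes[keep]
            preds.append((boxes, scores, classes))
    return preds


def evaluate(model: Model, manifest: DatasetManifest, split: str = "val",
             runs: int = 1, seed: int = 0, input_size: int | None = None,
             conf_threshold: float = 0.05, iou_threshold: float = 0.45):
    """Evaluate on a split; with ``runs`` > 1 the image set is bootstrap
    resampled per run and mAP/P/R are summarised as mean +/- sample std.

    Returns (list of EvalReport, dict of RunStatistics).
    """
    items = manifest.subset(split).items or manifest.items
    if not items:
        raise ValueError(f"no items in split {split!r}")
    missing = [it for it in items if not os.path.exists(it.label)]
    for it in missing[:5]:
        warnings.warn(f"missing label file {it.label}")
    if len(missing) > 0.1 * len(items):
        raise ValueError(f"{len(missing)}/{len(items)} label files missing")
    size = input_size or model.spec.input_size
    preds = predict(model, items, size, conf_threshold, iou_threshold)
    truths = []
    for it in items:
        labels = read_labels(it.label) if os.path.exists(it.label) else []
        truths.append((np.array([lb.to_xyxy(size, size) for lb in labels]
                                ).reshape(-1, 4),
                       np.array([lb.class_id for lb in labels], int)))
    rng = np.random.default_rng(seed)
    reports = []
    for r in range(runs):
        idx = np.arange(len(items)) if runs == 1 else \
            rng.integers(0, len(items), len(items))
        reports.append(evalkit.evaluate_detections(
            [preds[i] for i in idx], [truths[i] for i in idx],
            model.spec.num_classes))
    stats = {
        "map_50_95": evalkit.run_statistics([r.map_50_95 for r in reports]),
        "map_50": evalkit.run_statistics([r.map_50 for r in reports]),
        "precision": evalkit.run_statistics([r.precision for r in reports]),
        "recall": evalkit.run_statistics([r.recall for r in reports]),
    }
    return reports, stats
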