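"""Detection evaluation: greedy matching, precision/recall, average
precision, mAP@0.5-0.95, and repeated-run mean +/- std summaries.

AP integrates the precision-recall curve with the 101-point interpolation of
the COCO convention (the precision envelope is monotonised and sampled at
recalls 0, 0.01, ..., 1); a continuous trapezoid mode is available. mAP is
the mean of per-class APs, averaged over the ten IoU matching thresholds
0.50:0.05:0.95. The headline P/R operating point is the confidence that
maximises F1 along the score sweep (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import box_iou

IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list                 # (det index, truth index, IoU)
    det_flags: np.ndarray       # per-detection 1 = matched (score-ordered)
    n_truths: int


def match_detections(det_boxes, det_scores, det_classes,
                     truth_boxes, truth_classes,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy same-class matching by descending score.

    Each detection takes the highest-IoU still-unmatched truth of its class
    with IoU >= threshold; leftover detections are false positives and
    unmatched truths false negatives.
    """
    det_boxes = np.asarray(det_boxes, float).reshape(-1, 4)
    truth_boxes = np.asarray(truth_boxes, float).reshape(-1, 4)
    det_scores = np.asarray(det_scores, float)
    det_classes = np.asarray(det_classes, int)
    truth_classes = np.asarray(truth_classes, int)
    order = np.argsort(-det_scores, kind="stable")
    iou = box_iou(det_boxes, truth_boxes) if len(det_boxes) and len(truth_boxes) \
        else np.zeros((len(det_boxes), len(truth_boxes)))
    taken = np.zeros(len(truth_boxes), bool)
    flags = np.zeros(len(det_boxes), int)
    pairs = []
    for i in order:
        cand = np.nonzero((truth_classes == det_classes[i]) & ~taken
                          & (iou[i] >= iou_threshold))[0]
        if len(cand):
            j = cand[np.argmax(iou[i, cand])]
            taken[j] = True
            flags[i] = 1
            pairs.append((int(i), int(j), float(iou[i, j])))
    tp = int(flags.sum())
    return MatchResult(tp=tp, fp=len(det_boxes) - tp,
                       fn=len(truth_boxes) - tp, pairs=pairs,
                       det_flags=flags[order], n_truths=len(truth_boxes))


def precision_recall(m: MatchResult) -> tuple:
    """P = TP/(TP+FP), R = TP/(TP+FN); the 0/0 case is 0 by convention."""
    if min(m.tp, m.fp, m.fn) < 0:
        raise ValueError("negative match counts")
    p = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    r = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    return p, r


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def average_precision(flags, n_truths: int, mode: str = "interp101") -> float:
    """AP from score-ordered TP(1)/FP(0) flags.

    ``interp101``: COCO 101-point interpolation of the monotone precision
    envelope; ``continuous``: exact area under the stepwise PR curve.
    """
    if n_truths < 0:
        raise ValueError("n_truths must be >= 0")
    flags = np.asarray(flags, dtype=float)
    if n_truths == 0 or flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(1.0 - flags)
    recall = tp / n_truths
    precision = tp / np.maximum(tp + fp, 1e-12)
    # monotone non-increasing envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if mode == "interp101":
        grid = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(vals.mean())
    if mode == "continuous":
        r = np.concatenate([[0.0], recall])
        e = np.concatenate([[env[0]], env])
        return float(np.sum((r[1:] - r[:-1]) * e[1:]))
    raise ValueError(f"unknown AP mode {mode!r}")


def map_50_95(per_class_aps) -> float:
    """Mean over classes and IoU thresholds (order-invariant).

    ``per_class_aps`` is a mapping or array of per-class AP values, each a
    sequence over the ten thresholds (or a scalar).
    """
    if isinstance(per_class_aps, dict):
        arrs = [np.atleast_1d(np.asarray(v, float))
                for v in per_class_aps.values()]
    else:
        arrs = [np.atleast_1d(np.asarray(v, float)) for v in per_class_aps]
    return float(np.mean([a.mean() for a in arrs]))


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    ap: dict                    # class id -> {iou threshold -> AP}
    precision: float            # at the F1-optimal confidence, IoU 0.5
    recall: float
    map_50_95: float
    map_50: float
    num_classes: int
    operating_confidence: float = 0.0

    def summary(self) -> str:
        return (f"P {100 * self.precision:.1f}%  R {100 * self.recall:.1f}%  "
                f"mAP@0.5 {100 * self.map_50:.1f}%  "
                f"mAP@0.5-0.95 {100 * self.map_50_95:.1f}%")


def evaluate_detections(predictions, truths, num_classes: int,
                        iou_thresholds=IOU_THRESHOLDS) -> EvalReport:
    """Corpus-level evaluation.

    ``predictions``: per image (boxes Nx4, scores N, classes N);
    ``truths``: per image (boxes Mx4, classes M).
    """
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align per image")
    aps = {c: {} for c in range(num_classes)}
    for thr in iou_thresholds:
        # pool score-ordered flags per class across the corpus
        per_class = {c: ([], 0) for c in range(num_classes)}
        for (pb, ps, pc), (tb, tc) in zip(predictions, truths):
            pc = np.asarray(pc, int)
            tc = np.asarray(tc, int)
            for c in range(num_classes):
                sel = pc == c
                m = match_detections(np.asarray(pb, float)[sel],
                                     np.asarray(ps, float)[sel],
                                     pc[sel],
                                     np.asarray(tb, float)[np.asarray(tc) == c],
                                     tc[tc == c], thr)
                flags, n = per_class[c]
                scores = np.asarray(ps, float)[sel]
                order = np.argsort(-scores, kind="stable")
                flags.extend(zip(scores[order], m.det_flags))
                per_class[c] = (flags, n + m.n_truths)
        for c, (flags, n) in per_class.items():
            if n == 0 and not flags:
                continue
            flags.sort(key=lambda t: -t[0])
            aps[c][float(thr)] = average_precision(
                [f for _, f in flags], n)
    aps = {c: v for c, v in aps.items() if v}

    # headline P/R at the F1-optimal confidence (IoU 0.5)
    best = (0.0, 0.0, 0.0, 0.0)  # f1, p, r, conf
    all_scores = np.concatenate(
        [np.asarray(p[1], float) for p in predictions]) if predictions else []
    for conf in np.unique(np.round(all_scores, 3))[::-1]:
        tp = fp = fn = 0
        for (pb, ps, pc), (tb, tc) in zip(predictions, truths):
            ps = np.asarray(ps, float)
            keep = ps >= conf
            m = match_detections(np.asarray(pb, float)[keep], ps[keep],
                                 np.asarray(pc, int)[keep],
                                 tb, tc, 0.5)
            tp += m.tp
            fp += m.fp
            fn += m.fn
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best[0]:
            best = (f1, p, r, float(conf))

    map5095 = map_50_95({c: list(v.values()) for c, v in aps.items()}) \
        if aps else 0.0
    map50 = map_50_95({c: [v.get(0.5, 0.0)] for c, v in aps.items()}) \
        if aps else 0.0
    return EvalReport(ap=aps, precision=best[1], recall=best[2],
                      map_50_95=map5095, map_50=map50,
                      num_classes=num_classes,
                      operating_confidence=best[3])


# ---------------------------------------------------------------------------
# repeated-run statistics
# ---------------------------------------------------------------------------

@dataclass
class RunStatistics:
    mean: float
    std: float                  # sample std (n - 1 denominator)
    n: int
    values: list = field(default_factory=list)

    def format(self, percent: bool = True) -> str:
        """"mean +/- std" to one decimal, in percent by default."""
        scale = 100.0 if percent else 1.0
        return f"{scale * self.mean:.1f} ± {scale * self.std:.1f}"


def run_statistics(values) -> RunStatistics:
    values = [float(v) for v in values]
    if not values:
        raise ValueError("need at least one run")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        warnings.warn("standard deviation of a single run reported as 0")
        return RunStatistics(mean, 0.0, 1, values)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return RunStatistics(mean, var ** 0.5, n, values)
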