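"""Detection metrics on a hand-made example.

Three ground-truth boxes and four detections: one exact hit, one slightly
shifted hit, one duplicate (suppressed truth already matched), one false
alarm. Shows greedy matching, precision/recall, per-threshold AP, and the
mean +/- std summary used for repeated runs.
"""

import numpy as np

from yolosda import evalkit as ek

truth = np.array([[10, 10, 50, 50], [100, 100, 160, 160], [30, 200, 90, 260]],
                 float)
truth_cls = np.array([0, 1, 0])

dets = np.array([
    [10, 10, 50, 50],      # exact hit, class 0
    [104, 104, 164, 164],  # shifted hit, class 1 (IoU ~0.78)
    [12, 12, 52, 52],      # duplicate of the first truth
    [300, 300, 340, 340],  # false alarm
])
scores = np.array([0.95, 0.9, 0.85, 0.6])
det_cls = np.array([0, 1, 0, 0])

m = ek.match_detections(dets, scores, det_cls, truth, truth_cls, 0.5)
p, r = ek.precision_recall(m)
print(f"at IoU 0.5: TP={m.tp} FP={m.fp} FN={m.fn}  ->  P={p:.2f} R={r:.2f}")

report = ek.evaluate_detections([(dets, scores, det_cls)],
                                [(truth, truth_cls)], num_classes=2)
print(f"AP by class at IoU 0.5 : "
      f"{ {c: round(v[0.5], 3) for c, v in report.ap.items()} }")
print(f"mAP@0.5      : {report.map_50:.3f}")
print(f"mAP@0.5-0.95 : {report.map_50_95:.3f}  "
      "(drops as the IoU threshold tightens: the shifted hit stops counting)")

stats = ek.run_statistics([0.921, 0.924, 0.919, 0.925, 0.922])
print(f"five repeated runs would be reported as: {stats.format()} %")
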