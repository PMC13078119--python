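"""Evaluation metrics: greedy matching vs an independent oracle (shapely
for the IoU arithmetic), closed-form precision/recall/AP values, mAP
averaging, and the repeated-run statistics."""

import numpy as np
import pytest

from yolosda import evalkit as ek


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_perfect_predictions_all_true_positives():
    boxes = np.array([[0, 0, 10, 10], [20, 20, 40, 40], [5, 50, 25, 70]],
                     float)
    classes = np.array([0, 1, 2])
    m = ek.match_detections(boxes, np.array([0.9, 0.8, 0.7]), classes,
                            boxes, classes, 0.5)
    assert (m.tp, m.fp, m.fn) == (3, 0, 0)


def test_below_threshold_detection_is_fp_and_fn():
    det = np.array([[0, 0, 10, 10]], float)      # IoU 0.4 vs truth
    truth = np.array([[0, 0, 10, 25]], float)
    m = ek.match_detections(det, np.array([0.9]), np.array([0]),
                            truth, np.array([0]), 0.5)
    assert (m.tp, m.fp, m.fn) == (0, 1, 1)


def test_each_truth_matched_at_most_once():
    det = np.array([[0, 0, 10, 10], [1, 1, 11, 11]], float)
    truth = np.array([[0, 0, 10, 10]], float)
    m = ek.match_detections(det, np.array([0.9, 0.8]), np.array([0, 0]),
                            truth, np.array([0]), 0.5)
    assert (m.tp, m.fp, m.fn) == (1, 1, 0)
    assert m.tp + m.fn == m.n_truths


def shapely_greedy_match(det_boxes, scores, det_cls, truth_boxes, truth_cls,
                         thr):
    """Independent matcher: score-ordered greedy with shapely IoU."""
    from shapely.geometry import box as sbox
    taken = set()
    tp = 0
    for i in sorted(range(len(scores)), key=lambda k: -scores[k]):
        best, best_iou = None, thr
        for j in range(len(truth_boxes)):
            if j in taken or truth_cls[j] != det_cls[i]:
                continue
            a = sbox(*det_boxes[i])
            b = sbox(*truth_boxes[j])
            iou = a.intersection(b).area / a.union(b).area
            if iou >= best_iou:
                best, best_iou = j, iou
        if best is not None:
            taken.add(best)
            tp += 1
    return tp


def test_random_case_matches_shapely_oracle(rng):
    for _ in range(15):
        dxy = rng.uniform(0, 60, (4, 2))
        dwh = rng.uniform(10, 40, (4, 2))
        det = np.concatenate([dxy, dxy + dwh], axis=1)
        txy = rng.uniform(0, 60, (3, 2))
        twh = rng.uniform(10, 40, (3, 2))
        truth = np.concatenate([txy, txy + twh], axis=1)
        scores = rng.uniform(size=4)
        dc = rng.integers(0, 2, 4)
        tc = rng.integers(0, 2, 3)
        m = ek.match_detections(det, scores, dc, truth, tc, 0.3)
        assert m.tp == shapely_greedy_match(det, scores, dc, truth, tc, 0.3)


def test_count_conservation(rng):
    det = rng.uniform(0, 50, (6, 2))
    det = np.concatenate([det, det + rng.uniform(5, 30, (6, 2))], axis=1)
    truth = rng.uniform(0, 50, (4, 2))
    truth = np.concatenate([truth, truth + rng.uniform(5, 30, (4, 2))], axis=1)
    m = ek.match_detections(det, rng.uniform(size=6), np.zeros(6, int),
                            truth, np.zeros(4, int), 0.5)
    assert m.tp + m.fp == 6 and m.tp + m.fn == 4


# ---------------------------------------------------------------------------
# precision / recall
# ---------------------------------------------------------------------------

def test_precision_recall_arithmetic():
    m = ek.MatchResult(tp=9, fp=1, fn=0, pairs=[], det_flags=np.ones(10),
                       n_truths=9)
    assert ek.precision_recall(m)[0] == pytest.approx(0.9)
    m = ek.MatchResult(tp=8, fp=0, fn=2, pairs=[], det_flags=np.ones(8),
                       n_truths=10)
    assert ek.precision_recall(m)[1] == pytest.approx(0.8)


def test_precision_recall_zero_convention_and_validation():
    m = ek.MatchResult(0, 0, 0, [], np.zeros(0), 0)
    assert ek.precision_recall(m) == (0.0, 0.0)
    with pytest.raises(ValueError, match="negative"):
        ek.precision_recall(ek.MatchResult(-1, 0, 0, [], np.zeros(0), 0))


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def test_perfect_detector_ap_is_one():
    assert ek.average_precision([1, 1, 1], 3) == pytest.approx(1.0)


def test_no_detections_ap_is_zero():
    assert ek.average_precision([], 5) == 0.0
    assert ek.average_precision([1, 1], 0) == 0.0


def test_ap_101_point_hand_enumerated_case():
    """Flags [tp, fp, tp] with 2 truths: P steps 1, 1/2, 2/3 at R 1/2, 1/2,
    1. The envelope is 1 for r <= 0.5 and 2/3 above, so the 101-point sum
    is (51 + 50 * 2/3) / 101."""
    expected = (51 + 50 * (2 / 3)) / 101
    assert ek.average_precision([1, 0, 1], 2) == pytest.approx(expected,
                                                               abs=1e-12)


def test_ap_continuous_mode_exact_area():
    # same case: area = 0.5 * 1 + 0.5 * (2/3)
    got = ek.average_precision([1, 0, 1], 2, mode="continuous")
    assert got == pytest.approx(0.5 + 0.5 * 2 / 3)


def test_ap_monotone_under_prepended_hit(rng):
    """Adding a correct top-ranked detection never decreases AP."""
    for _ in range(30):
        flags = list((rng.uniform(size=8) > 0.5).astype(int))
        n = int(sum(flags) + rng.integers(0, 3))
        if n == 0:
            continue
        base = ek.average_precision(flags, n)
        better = ek.average_precision([1] + flags, n + 1)
        assert better >= base - 1e-12


def test_map_averaging():
    assert ek.map_50_95({0: [1.0] * 10, 1: [1.0] * 10}) == 1.0
    assert ek.map_50_95({0: [0.5], 1: [1.0]}) == pytest.approx(0.75)


def test_map_random_grid_equals_direct_mean(rng):
    grid = rng.uniform(size=(6, 10))
    got = ek.map_50_95({c: grid[c] for c in range(6)})
    assert got == pytest.approx(grid.mean())


def test_threshold_monotonicity_of_ap(rng):
    """AP at IoU 0.95 never exceeds AP at IoU 0.5 for the same detections."""
    truth_xy = rng.uniform(0, 50, (5, 2))
    truth = np.concatenate([truth_xy, truth_xy + 20], axis=1)
    jitter = rng.normal(0, 3, truth.shape)
    preds = [(truth + jitter, rng.uniform(0.5, 1, 5), np.zeros(5, int))]
    truths = [(truth, np.zeros(5, int))]
    rep = ek.evaluate_detections(preds, truths, num_classes=1)
    assert rep.ap[0][0.95] <= rep.ap[0][0.5] + 1e-12


def test_ground_truth_as_predictions_gives_map_one():
    truth = np.array([[0, 0, 20, 20], [30, 30, 60, 60]], float)
    classes = np.array([0, 1])
    preds = [(truth, np.array([0.9, 0.9]), classes)]
    rep = ek.evaluate_detections(preds, [(truth, classes)], num_classes=6)
    assert rep.map_50_95 == pytest.approx(1.0)
    assert rep.precision == pytest.approx(1.0)
    assert rep.recall == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# run statistics
# ---------------------------------------------------------------------------

def test_run_statistics_closed_form():
    st = ek.run_statistics([1, 2, 3])
    assert st.mean == pytest.approx(2.0) and st.std == pytest.approx(1.0)


def test_run_statistics_constant_runs():
    assert ek.run_statistics([5, 5, 5, 5, 5]).std == 0.0


def test_run_statistics_matches_two_pass_oracle(rng):
    vals = rng.uniform(size=5).tolist()
    st = ek.run_statistics(vals)
    mean = sum(vals) / 5
    s = (sum((v - mean) ** 2 for v in vals) / 4) ** 0.5
    assert st.mean == pytest.approx(mean) and st.std == pytest.approx(s)


def test_run_statistics_single_run_warns_and_errors():
    with pytest.warns(UserWarning):
        st = ek.run_statistics([0.7])
    assert st.std == 0.0 and st.n == 1
    with pytest.raises(ValueError):
        ek.run_statistics([])


def test_mean_std_report_format():
    st = ek.run_statistics([0.992, 0.994, 0.993])
    assert st.format() == "99.3 ± 0.1"
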