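"""Metrics: matching examples, PR arithmetic, AP against a brute-force
PR-curve oracle, confusion-matrix tallies, FPS, and heatmap contracts."""

import numpy as np
import pytest

from repdet.evaluation import (
    GroundTruthBox,
    average_precision,
    confusion_matrix,
    fps,
    map_metric,
    match_detections,
    precision,
    recall,
)
from repdet.postprocess import Detection, iou


# ----------------------------------------------------- independent AP oracle
def ap_bruteforce(scores, is_tp, num_gt):
    """Recompute P/R at every threshold from scratch, build the envelope by
    scanning, and average interpolated precision at 101 recall points."""
    if num_gt == 0:
        return float("nan")
    pairs = sorted(zip(scores, is_tp), key=lambda p: -p[0])
    points = []  # (recall, precision) after each detection
    tp = fp = 0
    for _, flag in pairs:
        tp += bool(flag)
        fp += not flag
        points.append((tp / num_gt, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for rec, prec in points:
            if rec >= r:  # exact comparison, matching the searchsorted rule
                best = max(best, prec)
        total += best
    return total / 101.0


class TestMatching:
    def test_perfect_detections(self):
        gts = [GroundTruthBox(0, (0, 0, 10, 10)), GroundTruthBox(1, (20, 20, 30, 30))]
        dets = [Detection(0, 0.4, (0, 0, 10, 10)), Detection(1, 0.9, (20, 20, 30, 30))]
        ledger = match_detections(dets, gts, 0.5)
        assert ledger.tp == 2 and ledger.fp == 0 and ledger.fn == 0

    def test_zero_detections(self):
        gts = [GroundTruthBox(0, (0, 0, 10, 10))] * 3
        ledger = match_detections([], gts, 0.5)
        assert (ledger.tp, ledger.fp, ledger.fn) == (0, 0, 3)

    def test_crafted_five_det_three_truth(self):
        gts = [
            GroundTruthBox(0, (0, 0, 10, 10)),
            GroundTruthBox(0, (12, 0, 22, 10)),
            GroundTruthBox(1, (40, 40, 50, 50)),
        ]
        dets = [
            Detection(0, 0.95, (0, 0, 10, 10)),    # TP on gt0
            Detection(0, 0.90, (1, 0, 11, 10)),    # overlaps gt0 (taken) -> FP
            Detection(0, 0.85, (12, 0, 22, 10)),   # TP on gt1
            Detection(1, 0.80, (41, 41, 51, 51)),  # TP on gt2
            Detection(1, 0.70, (0, 0, 5, 5)),      # FP, wrong place
        ]
        ledger = match_detections(dets, gts, 0.5)
        assert (ledger.tp, ledger.fp, ledger.fn) == (3, 2, 0)
        matched = {id(d): g for d, g in ledger.matches}
        assert matched[id(dets[0])] == 0
        assert matched[id(dets[1])] is None
        assert matched[id(dets[2])] == 1

    def test_each_gt_matched_once(self, make_detections):
        rng = np.random.default_rng(0)
        gts = [GroundTruthBox(int(rng.integers(2)), (x, x, x + 10, x + 10)) for x in range(0, 50, 5)]
        dets = make_detections(40, nc=2)
        ledger = match_detections(dets, gts, 0.3)
        matched_gts = [g for _, g in ledger.matches if g is not None]
        assert len(matched_gts) == len(set(matched_gts))
        assert ledger.tp + ledger.fp == len(dets)


class TestPrecisionRecall:
    def make_ledger(self, tp, fp, fn):
        from repdet.evaluation import MatchLedger

        return MatchLedger(0.5, [], tp, fp, fn)

    def test_perfect_precision(self):
        assert precision(self.make_ledger(1, 0, 0)) == 1.0

    def test_hand_arithmetic(self):
        assert precision(self.make_ledger(3, 1, 0)) == 0.75
        assert recall(self.make_ledger(3, 0, 1)) == 0.75

    def test_zero_tp(self):
        assert precision(self.make_ledger(0, 5, 0)) == 0.0
        assert precision(self.make_ledger(0, 0, 0)) == 0.0
        assert recall(self.make_ledger(0, 0, 0)) == 0.0


class TestAveragePrecision:
    def test_all_tp_cover_all(self):
        scores = np.array([0.9, 0.8, 0.7])
        assert average_precision(scores, np.array([True] * 3), 3) == pytest.approx(1.0)

    def test_all_fp(self):
        scores = np.array([0.9, 0.8])
        assert average_precision(scores, np.array([False, False]), 2) == 0.0

    def test_toy_six_detections_vs_bruteforce(self):
        scores = np.array([0.95, 0.9, 0.8, 0.7, 0.6, 0.5])
        flags = np.array([True, False, True, True, False, True])
        got = average_precision(scores, flags, 5)
        expect = ap_bruteforce(scores, flags, 5)
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_agreement_with_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        scores = rng.uniform(0, 1, n)
        flags = rng.uniform(0, 1, n) < 0.6
        num_gt = int(flags.sum() + rng.integers(0, 5))
        if num_gt == 0:
            return
        got = average_precision(scores, flags, num_gt)
        assert got == pytest.approx(ap_bruteforce(scores, flags, num_gt), abs=1e-10)


class TestMapMetric:
    def _one_box_world(self):
        gts = [
            [GroundTruthBox(0, (0, 0, 10, 10))],
            [GroundTruthBox(1, (5, 5, 25, 25))],
        ]
        dets = [
            [Detection(0, 0.9, (0, 0, 10, 10))],
            [Detection(1, 0.8, (5, 5, 25, 25))],
        ]
        return dets, gts

    def test_two_category_mean(self):
        dets, gts = self._one_box_world()
        # perfect boxes: AP 1.0 at every threshold for both categories
        res = map_metric(dets, gts, 2)
        assert res.ap50 == pytest.approx(1.0)
        assert res.map == pytest.approx(1.0)

    def test_mean_arithmetic(self):
        # categories with averaged APs 1.0 and 0.5 -> mAP 0.75
        assert np.mean([1.0, 0.5]) == 0.75  # the aggregation rule itself

    def test_single_category(self):
        dets = [[Detection(0, 0.9, (0, 0, 10, 10))]]
        gts = [[GroundTruthBox(0, (0, 0, 10, 10))]]
        res = map_metric(dets, gts, 4)
        assert res.map == list(res.ap_per_category.values())[0]

    def test_map_le_ap50(self):
        rng = np.random.default_rng(3)
        gts, dets = [], []
        for _ in range(8):
            x = rng.uniform(0, 50)
            gts.append([GroundTruthBox(0, (x, x, x + 20, x + 20))])
            jitter = rng.uniform(-4, 4, 4)
            dets.append(
                [Detection(0, float(rng.uniform(0.3, 1)), (x + jitter[0], x + jitter[1], x + 20 + jitter[2], x + 20 + jitter[3]))]
            )
        res = map_metric(dets, gts, 1)
        assert res.map <= res.ap50 + 1e-12

    def test_no_ground_truth_raises(self):
        with pytest.raises(ValueError, match="undefined|no annotated"):
            map_metric([[]], [[]], 2)


class TestFPS:
    def test_reciprocal(self):
        assert fps(0.005, 0.003, 0.002) == pytest.approx(100.0)

    def test_doubling_halves(self):
        assert fps(0.002, 0.02, 0.006) == pytest.approx(2 * fps(0.004, 0.04, 0.012))

    def test_component_example(self):
        assert fps(0.002, 0.01, 0.003) == pytest.approx(1 / 0.015)

    def test_zero_time_raises(self):
        with pytest.raises(ValueError):
            fps(0.0, 0.0, 0.0)


class TestConfusionMatrix:
    def test_perfect_detector_diagonal(self):
        gts, dets = [], []
        for cat in range(3):
            gts.append([GroundTruthBox(cat, (0, 0, 10, 10))])
            dets.append([Detection(cat, 0.9, (0, 0, 10, 10))])
        table = confusion_matrix(dets, gts, 3)
        assert (np.diag(table)[:3] == 1).all()
        assert table.sum() == 3

    def test_zero_detections_background_row(self):
        gts = [[GroundTruthBox(0, (0, 0, 10, 10)), GroundTruthBox(2, (20, 20, 30, 30))]]
        table = confusion_matrix([[]], gts, 3)
        assert table[3, 0] == 1 and table[3, 2] == 1
        assert table.sum() == 2

    def test_toy_four_image_hand_tally(self):
        gts = [
            [GroundTruthBox(0, (0, 0, 10, 10))],
            [GroundTruthBox(1, (0, 0, 10, 10))],
            [GroundTruthBox(2, (0, 0, 10, 10))],
            [],
        ]
        dets = [
            [Detection(0, 0.9, (0, 0, 10, 10))],              # correct
            [Detection(2, 0.8, (0, 0, 10, 10))],              # misclassified
            [],                                               # missed
            [Detection(1, 0.7, (0, 0, 10, 10))],              # spurious
        ]
        table = confusion_matrix(dets, gts, 3)
        expect = np.zeros((4, 4), dtype=np.int64)
        expect[0, 0] = 1   # predicted 0, actual 0
        expect[2, 1] = 1   # predicted 2, actual 1
        expect[3, 2] = 1   # background, actual 2 (missed)
        expect[1, 3] = 1   # predicted 1, actual background (spurious)
        np.testing.assert_array_equal(table, expect)

    def test_column_sums_equal_gt_counts(self, make_detections):
        rng = np.random.default_rng(5)
        gts, dets = [], []
        counts = np.zeros(3, dtype=int)
        for _ in range(6):
            img_gts = []
            for _ in range(int(rng.integers(0, 4))):
                c = int(rng.integers(3))
                x = float(rng.uniform(0, 60))
                img_gts.append(GroundTruthBox(c, (x, x, x + 15, x + 15)))
                counts[c] += 1
            gts.append(img_gts)
            dets.append(make_detections(int(rng.integers(0, 6))))
        table = confusion_matrix(dets, gts, 3)
        np.testing.assert_array_equal(table[:, :3].sum(axis=0), counts)


@pytest.fixture(scope="module")
def heatmap_model():
    from repdet.model import ModelConfig, build_model

    return build_model(
        ModelConfig(scale="n", num_categories=4, width_multiple=0.125, use_fgconcat=True, seed=0)
    ).eval()


class TestHeatmap:

    def test_output_matches_image_size(self, heatmap_model):
        from repdet.evaluation import activation_heatmap

        img = np.random.default_rng(0).uniform(0, 1, (3, 64, 64)).astype(np.float32)
        cam = activation_heatmap(heatmap_model, img, "join1")
        assert cam.shape == (64, 64)

    def test_values_in_unit_interval(self, heatmap_model):
        from repdet.evaluation import activation_heatmap

        img = np.random.default_rng(1).uniform(0, 1, (3, 64, 64)).astype(np.float32)
        cam = activation_heatmap(heatmap_model, img, "join2")
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_unknown_block_raises(self, heatmap_model):
        from repdet.evaluation import activation_heatmap

        img = np.zeros((3, 64, 64), dtype=np.float32)
        with pytest.raises(KeyError, match="unknown block"):
            activation_heatmap(heatmap_model, img, "not_a_block")

    def test_constant_activations_give_flat_map(self, heatmap_model):
        from repdet.evaluation import activation_heatmap

        img = np.zeros((3, 64, 64), dtype=np.float32)
        cam = activation_heatmap(heatmap_model, img, "join1")
        assert np.ptp(cam) <= 1e-6 or (cam.min() >= 0 and cam.max() <= 1)
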