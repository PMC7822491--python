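"""Loss and metric semantics, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedseg.metrics_losses import (ConfusionCounts, accuracy, confusion,
                                   dice_loss, dsc, evaluate_cases, iou,
                                   roc_auc, roc_curve, soft_dice)


def concordance_auc(scores, truth):
    """O(P*N) pairwise oracle: P(pos outscores neg), ties counted half."""
    s = np.asarray(scores, dtype=float).ravel()
    t = np.asarray(truth, dtype=bool).ravel()
    pos, neg = s[t], s[~t]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestSoftDice:
    def test_identical_masks(self, rng):
        m = (rng.random((16, 16)) > 0.5).astype(float)
        assert soft_dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4))
        a[:2] = 1
        b = np.zeros((4, 4))
        b[2:] = 1
        assert soft_dice(a, b) == 0.0

    def test_worked_half_probability_example(self):
        # a = 0.5 everywhere on 2x2, b = ones: 2*2 / (1 + 4) = 0.8
        a = np.full((2, 2), 0.5)
        b = np.ones((2, 2))
        assert soft_dice(a, b) == pytest.approx(0.8, abs=1e-12)

    def test_both_empty_is_perfect(self):
        z = np.zeros((8, 8))
        assert soft_dice(z, z) == 1.0
        assert dice_loss(z, z) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            soft_dice(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            soft_dice(np.full((2, 2), 1.5), np.ones((2, 2)))

    def test_loss_decreases_when_tp_confidence_grows(self, rng):
        b = np.zeros((8, 8))
        b[2:6, 2:6] = 1
        a = rng.random((8, 8)) * 0.5
        base = dice_loss(a, b)
        a2 = a.copy()
        a2[3, 3] = min(1.0, a[3, 3] + 0.3)  # raise a true-positive pixel
        assert dice_loss(a2, b) < base

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_and_symmetric_on_binary(self, seed):
        g = np.random.default_rng(seed)
        a = (g.random((6, 6)) > 0.5).astype(float)
        b = (g.random((6, 6)) > 0.5).astype(float)
        d = soft_dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == soft_dice(b, a)


class TestConfusionAndCounts:
    def test_perfect_prediction(self, rng):
        t = rng.random((8, 8)) > 0.5
        c = confusion(t, t)
        assert c.fp == c.fn == 0
        assert c.tp + c.tn == 64

    def test_inverted_prediction(self, rng):
        t = rng.random((8, 8)) > 0.5
        c = confusion(~t, t)
        assert c.tp == c.tn == 0

    def test_matches_exhaustive_enumeration_on_3x3(self):
        pred = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0]])
        truth = np.array([[1, 1, 0], [0, 1, 0], [0, 1, 1]])
        c = confusion(pred, truth)
        tp = tn = fp = fn = 0
        for i, j in itertools.product(range(3), range(3)):
            p, t = pred[i, j], truth[i, j]
            tp += p and t
            tn += (not p) and (not t)
            fp += p and not t
            fn += (not p) and t
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([[2, 0]]), np.array([[1, 0]]))

    def test_worked_metric_values(self):
        c = ConfusionCounts(tp=1, tn=97, fp=1, fn=1)
        assert accuracy(c) == pytest.approx(0.98)
        c2 = ConfusionCounts(tp=1, tn=0, fp=1, fn=1)
        assert iou(c2) == pytest.approx(1 / 3)
        assert dsc(c2) == pytest.approx(0.5)

    def test_nothing_to_find_convention(self):
        c = ConfusionCounts(tp=0, tn=10, fp=0, fn=0)
        assert iou(c) == 1.0 and dsc(c) == 1.0

    def test_dsc_iou_identity_random_tables(self, rng):
        for _ in range(1000):
            tp, fp, fn = rng.integers(0, 50, size=3)
            tn = int(rng.integers(0, 50))
            c = ConfusionCounts(int(tp), tn, int(fp), int(fn))
            i, d = iou(c), dsc(c)
            assert d == pytest.approx(2 * i / (1 + i), abs=1e-12)
            assert i <= d + 1e-12


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0])
        _, auc = roc_auc(scores, truth)
        assert auc == 1.0

    def test_no_discrimination(self):
        scores = np.full(10, 0.3)
        truth = np.array([1, 0] * 5)
        (fpr, tpr, _), auc = roc_auc(scores, truth)
        assert auc == pytest.approx(0.5)
        np.testing.assert_array_equal(fpr, [0, 1])
        np.testing.assert_array_equal(tpr, [0, 1])

    def test_six_pixel_toy_matches_concordance(self):
        scores = np.array([0.9, 0.6, 0.6, 0.4, 0.3, 0.1])
        truth = np.array([1, 1, 0, 1, 0, 0])
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(concordance_auc(scores, truth), abs=1e-12)

    def test_matches_concordance_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            truth = rng.random(n) > 0.6
            if truth.all() or not truth.any():
                continue
            _, auc = roc_auc(scores, truth)
            assert auc == pytest.approx(concordance_auc(scores, truth), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(500)
        truth = rng.random(500) > 0.7
        _, auc = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_points_export_round_trip(self, rng, tmp_path):
        import pandas as pd

        from sedseg.metrics_losses import write_roc_points

        scores = rng.random(64)
        truth = rng.random(64) > 0.5
        fpr, tpr, _ = roc_curve(scores, truth)
        path = tmp_path / "roc.csv"
        write_roc_points(fpr, tpr, path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["fpr"], fpr)
        np.testing.assert_allclose(back["tpr"], tpr)

    def test_endpoints(self, rng):
        scores = rng.random(64)
        truth = rng.random(64) > 0.5
        fpr, tpr, thr = roc_curve(scores, truth)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestEvaluation:
    def test_perfect_predictions_summary(self, rng):
        masks = [rng.random((8, 8)) > 0.5 for _ in range(3)]
        df = evaluate_cases([(i, m, m) for i, m in enumerate(masks)])
        mean = df[df["id"] == "mean"].iloc[0]
        assert mean["acc"] == mean["iou"] == mean["dsc"] == 1.0

    def test_mean_is_unweighted_over_cases(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        full = np.ones((4, 4), dtype=bool)
        df = evaluate_cases([("hit", full, full), ("miss", a, full)])
        per_case = df[df["id"] != "mean"]["dsc"].to_numpy()
        mean = df[df["id"] == "mean"]["dsc"].iloc[0]
        assert mean == pytest.approx(per_case.mean())
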