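"""Metric correctness against brute-force enumeration and the published
per-tooth tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import toothseg as ts
from toothseg.evaluation import (BinaryCounts, tooth_metrics,
                                 per_tooth_counts, CONFUSION_LABELS)


def brute_force_counts(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


class TestBinaryCounts:
    def test_perfect_prediction(self):
        truth = np.zeros((25, 40), dtype=int)
        truth.ravel()[:100] = 1
        c = ts.binary_counts(truth, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (100, 0, 0, 900)

    def test_all_negative_prediction(self):
        truth = np.zeros((10, 10), dtype=int)
        truth.ravel()[:50] = 1
        c = ts.binary_counts(np.zeros_like(truth), truth)
        assert (c.tp, c.fn) == (0, 50) and c.fp == 0

    def test_random_planes_match_per_pixel_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pred = rng.integers(0, 2, size=(8, 8))
            truth = rng.integers(0, 2, size=(8, 8))
            c = ts.binary_counts(pred, truth)
            assert (c.tp, c.fp, c.fn, c.tn) == brute_force_counts(pred, truth)
            assert c.total == 64

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ts.binary_counts(np.full((2, 2), 0.5), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="mismatch"):
            ts.binary_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetricFormulas:
    def test_symmetric_counts(self):
        c = BinaryCounts(tp=1, fp=1, fn=1, tn=0)
        assert ts.precision(c) == ts.recall(c) == ts.f1(c) == 0.5
        assert np.isclose(ts.iou(c), 1 / 3)
        # Dice-Jaccard identity on the same counts
        assert np.isclose(ts.iou(c), ts.f1(c) / (2 - ts.f1(c)))

    def test_tooth11_published_precision_recall_reproduce_f1_and_iou(self):
        # printed precision/recall of the best-segmented central incisor
        p, r = 0.9452, 0.9465
        f1 = 2 * p * r / (p + r)
        assert abs(100 * f1 - 94.59) < 0.01
        assert abs(100 * f1 / (2 - f1) - 89.74) < 0.015

    def test_zero_denominators_flagged_not_nan(self):
        m = tooth_metrics(BinaryCounts(0, 0, 0, 100))
        assert m.absent
        assert m.precision == m.recall == m.f1 == m.iou == 0.0
        assert m.accuracy == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 10**6)] * 4))
    def test_any_counts_satisfy_dice_jaccard_and_bounds(self, quad):
        c = BinaryCounts(*quad)
        d, j = ts.f1(c), ts.iou(c)
        assert np.isclose(j, d / (2 - d), atol=1e-12)
        for v in (ts.precision(c), ts.recall(c), d, j):
            assert 0.0 <= v <= 1.0
        if c.total:
            assert 0.0 <= ts.accuracy(c) <= 1.0


class TestPerToothReport:
    def test_perfect_prediction_rows_all_100(self, small_scene):
        _, masks = small_scene
        rep = ts.per_tooth_report(masks.planes, masks.planes)
        body = rep.table.drop(index="Average")
        assert np.allclose(body.values, 100.0)
        assert np.allclose(rep.average.values, 100.0)

    def test_single_pair_matches_brute_force_per_channel(self):
        rng = np.random.default_rng(2)
        pred = rng.integers(0, 2, size=(16, 16, 32))
        truth = rng.integers(0, 2, size=(16, 16, 32))
        counts = per_tooth_counts(pred, truth)
        for ch in range(32):
            assert (counts[ch].tp, counts[ch].fp, counts[ch].fn,
                    counts[ch].tn) == brute_force_counts(pred[..., ch],
                                                         truth[..., ch])

    def test_average_row_is_unweighted_mean(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(0, 2, size=(2, 8, 8, 32))
        truth = rng.integers(0, 2, size=(2, 8, 8, 32))
        rep = ts.per_tooth_report(pred, truth)
        body = rep.table.drop(index="Average")
        assert np.allclose(rep.average.values, body.mean(axis=0).values)
        assert len(body) == 32


class TestPublishedTables:
    def test_published_macro_row_recomputed_from_per_tooth_rows(self):
        t3 = ts.load_published_sigmoid_table()
        avg = ts.macro_average(t3).round(2)
        assert avg["F1-Score"] == 92.66
        assert avg["mIoU"] == 86.39
        assert avg["Precision"] == 92.84
        assert avg["Recall"] == 92.49
        assert avg["Acc"] == 99.93

    def test_published_softmax_macro_recomputed(self):
        t4 = ts.load_published_comparison_table()
        avg = ts.macro_average(t4).round(2)
        assert avg["SoftMax F1-Score"] == 91.51
        assert avg["SoftMax mIoU"] == 84.58

    def test_published_rows_satisfy_metric_identities(self):
        body = ts.load_published_sigmoid_table().drop(index="Average") / 100.0
        P, R = body["Precision"], body["Recall"]
        F, J = body["F1-Score"], body["mIoU"]
        assert (abs(2 * P * R / (P + R) - F) * 100 < 0.015).all()
        assert (abs(F / (2 - F) - J) * 100 < 0.015).all()

    def test_published_confusion_row_recall_for_third_molar(self):
        t5 = ts.load_published_confusion_matrix()
        row = t5.loc["18"]
        recall_18 = row["18"] / row.sum()
        assert abs(recall_18 - 0.9201) < 0.0005
        # grand total = 62 test images at 256 x 512
        assert t5.values.sum() == 62 * 256 * 512


class TestConfusionMatrix:
    def test_perfect_one_tooth_scene_all_diagonal(self):
        lm = ts.build_fdi_label_map()
        planes = np.zeros((1, 8, 8, 32), dtype=int)
        planes[0, 2:5, 2:5, lm.channel_of(11)] = 1
        probs = planes.astype(float) * 0.9
        cm = ts.pixel_confusion_matrix(probs, planes, 0.5)
        assert cm.loc["11", "11"] == 9
        assert cm.loc["Background", "Background"] == 64 - 9
        off_diag = cm.values - np.diag(np.diag(cm.values))
        assert off_diag.sum() == 0

    def test_total_count_conserved(self):
        rng = np.random.default_rng(4)
        probs = rng.random((3, 8, 8, 32))
        truth = rng.integers(0, 2, size=(3, 8, 8, 32))
        cm = ts.pixel_confusion_matrix(probs, truth, 0.5)
        assert cm.values.sum() == 3 * 8 * 8
        assert cm.shape == (33, 33)
        assert list(cm.index) == CONFUSION_LABELS

    def test_matches_exhaustive_enumeration(self):
        lm = ts.build_fdi_label_map()
        rng = np.random.default_rng(5)
        probs = rng.random((1, 6, 6, 32))
        truth = rng.integers(0, 2, size=(1, 6, 6, 32))
        cm = ts.pixel_confusion_matrix(probs, truth, 0.5)
        expect = np.zeros((33, 33), dtype=int)
        order = {str(c): i + 1 for i, c in enumerate(sorted(lm.codes))}
        for y in range(6):
            for x in range(6):
                above = [ch for ch in range(32) if probs[0, y, x, ch] > 0.5]
                if above:
                    best = max(above, key=lambda ch: (probs[0, y, x, ch], -ch))
                    pl = order[str(lm.code_of(best))]
                else:
                    pl = 0
                tr = [ch for ch in range(32) if truth[0, y, x, ch]]
                tl = order[str(lm.code_of(tr[0]))] if tr else 0
                expect[tl, pl] += 1
        assert (cm.values == expect).all()
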