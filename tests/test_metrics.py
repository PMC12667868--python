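import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from stomaseg.io import label_objects
from stomaseg.metrics import (
    OVERLAY_PALETTE,
    aggregate_object_counts,
    classify_annotations,
    concordance_overlay,
    evaluate_dataset,
    fold_error_from_counts,
    margin_metrics,
    match_objects,
    pixel_contingency,
)
from stomaseg.synth import generate_toy_mask

from .conftest import random_mask
from .reference_counts import CONTINGENCY_ROWS, DETECTION_COUNTS


def _square(shape, r0, c0, size):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + size, c0 : c0 + size] = True
    return m


class TestPixelContingency:
    def test_identical_masks(self):
        m = random_mask(0)
        c = pixel_contingency(m, m)
        assert c.iou == 1.0 and c.total_pixel_error == 0

    def test_disjoint_masks(self):
        a = _square((32, 32), 2, 2, 5)
        b = _square((32, 32), 20, 20, 5)
        assert pixel_contingency(a, b).iou == 0.0

    def test_half_overlapping_squares(self):
        # two 100-px squares overlapping on 50 px: IoU = 50 / 150
        a = _square((40, 40), 10, 10, 10)
        b = _square((40, 40), 10, 15, 10)
        c = pixel_contingency(a, b)
        assert c.tp == 50 and c.fp == 50 and c.fn == 50
        assert c.iou == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_and_symmetry(self, seed):
        a, b = random_mask(seed), random_mask(seed + 100)
        c = pixel_contingency(a, b)
        assert c.tp + c.fp + c.fn + c.tn == a.size
        assert c.iou == pixel_contingency(b, a).iou

    def test_empty_pair_iou_is_one(self):
        z = np.zeros((8, 8), dtype=bool)
        assert pixel_contingency(z, z).iou == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_contingency(np.zeros((4, 4), dtype=bool), np.zeros((4, 5), dtype=bool))


class TestMarginMetrics:
    @pytest.mark.parametrize("image_id,_, __, margin, err, expected", CONTINGENCY_ROWS)
    def test_fold_error_arithmetic(self, image_id, _, __, margin, err, expected):
        assert round(fold_error_from_counts(err, margin), 1) == expected

    def test_perfect_prediction_zero_fold_error(self):
        m = _square((64, 64), 10, 10, 20)
        mm = margin_metrics(m, pixel_contingency(m, m), band_radius=1)
        assert mm.fold_error_magnitude == 0.0
        assert mm.margin_pixels > 0

    def test_band_hugs_the_boundary(self):
        m = _square((64, 64), 20, 20, 10)
        cont = pixel_contingency(m, m)
        thin = margin_metrics(m, cont, band_radius=1).margin_pixels
        wide = margin_metrics(m, cont, band_radius=3).margin_pixels
        assert 0 < thin < wide

    def test_empty_truth_rejected(self):
        z = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            margin_metrics(z, pixel_contingency(z, z))


class TestMatchObjects:
    def test_single_overlapping_pair(self):
        t = _square((32, 32), 5, 5, 8)
        p = _square((32, 32), 6, 6, 8)
        matches, stray = match_objects(label_objects(t), label_objects(p))
        assert matches == [(1, 1)] and stray == []

    def test_truth_without_prediction(self):
        t = _square((32, 32), 5, 5, 8)
        p = np.zeros((32, 32), dtype=bool)
        matches, stray = match_objects(label_objects(t), label_objects(p))
        assert matches == [(1, None)] and stray == []

    def test_one_pred_spanning_two_truths_takes_higher_iou(self):
        t = np.zeros((40, 60), dtype=bool)
        t[10:20, 5:15] = True  # truth 1
        t[10:20, 30:50] = True  # truth 2, bigger overlap with pred
        p = np.zeros((40, 60), dtype=bool)
        p[10:20, 12:50] = True  # spans both
        matches, stray = match_objects(label_objects(t), label_objects(p))
        assert (2, 1) in matches and (1, None) in matches
        assert stray == []

    def test_zero_overlap_never_matches(self):
        t = _square((32, 32), 2, 2, 5)
        p = _square((32, 32), 20, 20, 5)
        matches, stray = match_objects(label_objects(t), label_objects(p))
        assert matches == [(1, None)] and stray == [1]


class TestClassifyAnnotations:
    def test_perfect_prediction_all_complete(self):
        t = generate_toy_mask([300, 400, 500])
        calls, summary = classify_annotations(t, t)
        assert summary["hit"] == 3 and summary["pct_accurate"] == 100.0
        assert all(c.call == "Complete" for c in calls)

    def test_dilated_prediction_is_partial(self):
        t = _square((64, 64), 20, 20, 12)
        p = ndimage.binary_dilation(t, iterations=5)
        _, summary = classify_annotations(t, p, tol=3)
        assert summary["partial"] == 1 and summary["hit"] == 0

    def test_slightly_dilated_prediction_is_complete(self):
        t = _square((64, 64), 20, 20, 12)
        p = ndimage.binary_dilation(t, iterations=2)
        _, summary = classify_annotations(t, p, tol=3)
        assert summary["hit"] == 1

    def test_missing_object_is_a_miss(self):
        t = generate_toy_mask([300, 400, 500])
        lab = label_objects(t)
        p = t & (lab.label_map != 2)
        _, summary = classify_annotations(t, p)
        assert summary == {
            "hit": 2,
            "partial": 0,
            "miss": 1,
            "false": 0,
            "total": 3,
            "positives": 2,
            "pct_accurate": pytest.approx(200 / 3),
        }

    def test_stray_prediction_is_false(self):
        t = _square((64, 64), 5, 5, 10)
        p = t | _square((64, 64), 40, 40, 10)
        calls, summary = classify_annotations(t, p)
        assert summary["false"] == 1
        assert sum(c.call == "False" for c in calls) == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_call_totals_partition_truth_objects(self, seed):
        t = random_mask(seed, shape=(80, 80), p=0.25)
        p = random_mask(seed + 50, shape=(80, 80), p=0.25)
        _, s = classify_annotations(t, p)
        assert s["hit"] + s["partial"] + s["miss"] == s["total"] == len(label_objects(t))
        assert s["positives"] == s["hit"] + s["partial"]


class TestConcordanceOverlay:
    def test_identical_masks_black_and_pink_only(self):
        m = _square((16, 16), 4, 4, 6)
        ovl = concordance_overlay(m, m)
        colors = {tuple(c) for c in ovl.reshape(-1, 3)}
        assert colors == {OVERLAY_PALETTE["tn"], OVERLAY_PALETTE["tp"]}

    def test_disjoint_masks_no_pink(self):
        a = _square((32, 32), 2, 2, 5)
        b = _square((32, 32), 20, 20, 5)
        colors = {tuple(c) for c in concordance_overlay(a, b).reshape(-1, 3)}
        assert colors == {OVERLAY_PALETTE["tn"], OVERLAY_PALETTE["fn"], OVERLAY_PALETTE["fp"]}

    def test_palette_is_a_bijection(self):
        assert len(set(OVERLAY_PALETTE.values())) == 4


class TestAggregation:
    def test_reference_counts_total_row(self):
        df = pd.DataFrame(
            [
                {"hit": h, "miss": m, "partial": p, "total": h + m + p}
                for _, h, m, p in DETECTION_COUNTS
            ]
        )
        # two images carried a single false detection each
        df["false"] = 0
        df.loc[[0, 1], "false"] = 1
        total = aggregate_object_counts(df)
        assert round(total["pct_accurate"], 2) == 86.01
        assert total["positives"] == 550
        assert total["mean_misses"] == pytest.approx(0.9)
        assert total["max_misses"] == 3
        assert total["mean_false"] == pytest.approx(0.05)

    def test_single_perfect_image_total_equals_row(self):
        t = generate_toy_mask([300, 400])
        df, total = evaluate_dataset([(t, t)])
        assert total["hit"] == df.loc[0, "hit"] == 2
        assert total["pct_accurate"] == 100.0
        assert total["mean_iou"] == 1.0

    def test_evaluate_dataset_report_columns(self, small_scene):
        pred = ndimage.binary_dilation(small_scene.truth_mask)
        df, total = evaluate_dataset([(small_scene.truth_mask, pred)])
        for col in ("hit", "miss", "partial", "false", "iou", "margin_pixels", "fold_error_magnitude"):
            assert col in df.columns
        assert 0 < df.loc[0, "iou"] < 1
        assert total["total"] == len(small_scene.object_table)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([])
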