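import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organoidseg.imaging import BinaryMask, GrayscaleImage
from organoidseg.metrics import (
    ConfusionCounts,
    aggregate,
    confusion,
    methods_table,
    metrics,
    overlay,
    pooled_metrics,
    results_table,
)


def brute_force_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Independent per-pixel tally via a plain Python Counter."""
    tally = Counter(zip(pred.ravel().tolist(), gt.ravel().tolist()))
    return ConfusionCounts(
        tp=tally[(1, 1)], fp=tally[(1, 0)], tn=tally[(0, 0)], fn=tally[(0, 1)]
    )


class TestConfusion:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        gt = BinaryMask((rng.random((32, 32)) > 0.5).astype(np.uint8))
        c = confusion(gt, gt)
        assert c.fp == c.fn == 0
        assert c.tp == int(gt.labels.sum())
        assert c.total == 32 * 32

    def test_four_pixel_hand_enumeration(self):
        gt = BinaryMask(np.array([[1, 1], [0, 0]], dtype=np.uint8))
        pred = BinaryMask(np.array([[1, 0], [1, 0]], dtype=np.uint8))
        c = confusion(pred, gt)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_counts_partition_frame_for_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = BinaryMask((rng.random((17, 23)) > rng.random()).astype(np.uint8))
            g = BinaryMask((rng.random((17, 23)) > rng.random()).astype(np.uint8))
            assert confusion(p, g).total == 17 * 23

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(
                BinaryMask(np.zeros((4, 4), dtype=np.uint8)),
                BinaryMask(np.zeros((4, 5), dtype=np.uint8)),
            )


class TestMetrics:
    def test_four_pixel_closed_forms(self):
        m = metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert m.dice == pytest.approx(1 / 2)
        assert m.accuracy == pytest.approx(1 / 2)
        assert m.sensitivity == pytest.approx(1 / 2)
        assert m.specificity == pytest.approx(1 / 2)
        assert m.precision == pytest.approx(1 / 2)
        assert m.f1 == pytest.approx(1 / 2)

    def test_perfect_and_disjoint_cases(self):
        perfect = metrics(ConfusionCounts(tp=10, fp=0, tn=20, fn=0))
        assert perfect.dice == perfect.f1 == perfect.sensitivity == perfect.accuracy == 1.0
        disjoint = metrics(ConfusionCounts(tp=0, fp=5, tn=10, fn=5))
        assert disjoint.dice == 0.0 and disjoint.sensitivity == 0.0

    def test_undefined_ratios_flagged_not_zeroed(self):
        empty_gt = metrics(ConfusionCounts(tp=0, fp=0, tn=16, fn=0))
        assert math.isnan(empty_gt.sensitivity)
        assert math.isnan(empty_gt.dice)
        assert "sensitivity" in empty_gt.undefined

    @settings(max_examples=200, derandomize=True)
    @given(
        tp=st.integers(0, 10_000), fp=st.integers(0, 10_000),
        tn=st.integers(0, 10_000), fn=st.integers(0, 10_000),
    )
    def test_f1_equals_dice_from_shared_counts(self, tp, fp, tn, fn):
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if not math.isnan(m.f1):
            assert m.f1 == pytest.approx(m.dice, abs=1e-12)
        for v in m.to_dict().values():
            assert math.isnan(v) or 0.0 <= v <= 1.0

    def test_agrees_with_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = (rng.random((64, 64)) > rng.random()).astype(np.uint8)
            g = (rng.random((64, 64)) > rng.random()).astype(np.uint8)
            ours = confusion(BinaryMask(p), BinaryMask(g))
            ref = brute_force_counts(p, g)
            assert ours == ref
            assert metrics(ours).to_dict() == metrics(ref).to_dict()


class TestAggregation:
    def test_singleton_is_identity_under_both_methods(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, tn=10, fn=2))
        for method in ("median", "mean"):
            agg = aggregate([m], method)
            assert agg.to_dict() == pytest.approx(m.to_dict())

    def test_median_vs_mean_order_statistics(self):
        sets = [
            metrics(ConfusionCounts(tp=1, fp=4, tn=0, fn=4)),   # dice 0.2
            metrics(ConfusionCounts(tp=8, fp=2, tn=0, fn=2)),   # dice 0.8
            metrics(ConfusionCounts(tp=8, fp=2, tn=0, fn=2)),   # dice 0.8
        ]
        assert aggregate(sets, "median").dice == pytest.approx(0.8)
        assert aggregate(sets, "mean").dice == pytest.approx(0.6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        sets = [
            metrics(ConfusionCounts(*rng.integers(0, 50, size=4).tolist()))
            for _ in range(7)
        ]
        a = aggregate(sets, "median").to_dict()
        b = aggregate(sets[::-1], "median").to_dict()
        assert a == b

    def test_nan_entries_excluded_and_counted(self):
        sets = [
            metrics(ConfusionCounts(tp=0, fp=0, tn=16, fn=0)),  # undefined dice
            metrics(ConfusionCounts(tp=5, fp=0, tn=10, fn=5)),  # dice 2/3
        ]
        agg = aggregate(sets)
        assert agg.dice == pytest.approx(2 / 3)
        assert "dice:1" in agg.undefined

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_pooled_f1_dice_identity_even_when_per_image_differs(self):
        counts = [
            ConfusionCounts(tp=5, fp=0, tn=10, fn=5),
            ConfusionCounts(tp=1, fp=9, tn=5, fn=1),
        ]
        pooled = pooled_metrics(counts)
        assert pooled.f1 == pytest.approx(pooled.dice)


class TestOverlay:
    def test_perfect_prediction_has_no_accents(self):
        rng = np.random.default_rng(0)
        gt = BinaryMask((rng.random((16, 16)) > 0.5).astype(np.uint8))
        img_rgb = overlay(gt, gt)
        accents = set(map(tuple, img_rgb.reshape(-1, 3)))
        assert accents <= {(0, 0, 0), (255, 255, 255)}

    def test_all_false_positive_saturation(self):
        gt = BinaryMask(np.zeros((8, 8), dtype=np.uint8))
        pred = BinaryMask(np.ones((8, 8), dtype=np.uint8))
        img_rgb = overlay(gt, pred, palette="pink-green")
        assert (img_rgb == np.array([255, 182, 193])).all(axis=-1).all()

    def test_accent_counts_match_confusion(self):
        rng = np.random.default_rng(5)
        gt = BinaryMask((rng.random((32, 32)) > 0.4).astype(np.uint8))
        pred = BinaryMask((rng.random((32, 32)) > 0.6).astype(np.uint8))
        c = confusion(pred, gt)
        for palette in ("pink-green", "purple-cyan"):
            img_rgb = overlay(gt, pred, palette=palette)
            from organoidseg.metrics import PALETTES

            fp_px = (img_rgb == np.array(PALETTES[palette]["fp"])).all(axis=-1).sum()
            fn_px = (img_rgb == np.array(PALETTES[palette]["fn"])).all(axis=-1).sum()
            assert (fp_px, fn_px) == (c.fp, c.fn)


class TestReports:
    @staticmethod
    def _fake_results():
        from organoidseg.training import FoldResult, LooLaunch

        rng = np.random.default_rng(0)
        out = []
        for arch in ("munet", "unet"):
            for strat in ("classic", "gaussian", "shot"):
                for held in ("000", "001"):
                    tp, fp, fn = rng.integers(1, 50, size=3).tolist()
                    counts = ConfusionCounts(tp=tp, fp=fp, tn=100, fn=fn)
                    launch = LooLaunch(arch, strat, held, ("002",), 2, 0)
                    out.append(
                        FoldResult(
                            launch=launch, predicted=None, counts=counts,
                            scores=metrics(counts), manifest=(), n_train=4,
                        )
                    )
        return out

    def test_grid_shape_and_row_max_flags(self):
        table = results_table(self._fake_results())
        strategies = ["classic", "gaussian", "shot"]
        assert sorted(table.index) == ["munet", "unet"]
        for arch in table.index:
            vals = table.loc[arch, strategies]
            flags = table.loc[arch, [f"{s}__best" for s in strategies]]
            assert flags.to_numpy().sum() >= 1
            best_cols = [s for s in strategies if table.loc[arch, f"{s}__best"]]
            assert all(vals[c] == vals.max() for c in best_cols)

    def test_methods_table_has_the_five_metric_rows(self):
        sets = [metrics(ConfusionCounts(5, 1, 20, 2)), metrics(ConfusionCounts(7, 2, 18, 1))]
        table = methods_table({"kmeans": sets, "munet": sets})
        assert list(table.index) == ["Dice", "F1-score", "Sensitivity", "Specificity", "Accuracy"]
        assert sorted(table.columns) == ["kmeans", "munet"]

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            results_table([])
        with pytest.raises(ValueError):
            methods_table({})
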