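"""Metric suite: IoU, matching, AP (vs brute force), CP, confusion, sizes."""

import numpy as np
import pytest

from phenomask import (
    SIZE_BINS,
    Category,
    MaskRegion,
    OrganInstance,
    Provenance,
    ScaleCalibration,
    SheetAnnotation,
    average_precision,
    confusion_matrix,
    counting_precision,
    evaluate_sheets,
    iou,
    match_instances,
    measurement_precision,
    measurement_statistics,
    sizewise_ap,
)
from phenomask.evaluation import instance_size_cm

from conftest import make_square


def square_mask(x, y, side):
    return MaskRegion.from_polygon(make_square(x, y, side))


def gt_sheet(instances, image_id="s", size=2000):
    return SheetAnnotation(image_id=image_id, width=size, height=size,
                           instances=instances, provenance=Provenance.FULL)


def pred_sheet(instances, image_id="s", size=2000):
    return SheetAnnotation(image_id=image_id, width=size, height=size,
                           instances=instances, provenance=Provenance.PREDICTED)


class TestIoU:
    def test_identity(self):
        m = square_mask(10, 10, 10)
        assert iou(m, square_mask(10, 10, 10)) == 1.0

    def test_disjoint(self):
        assert iou(square_mask(0, 0, 10), square_mask(50, 50, 10)) == 0.0

    def test_offset_squares_one_third(self):
        # two 10x10 squares offset 5 px: 50 / 150
        assert iou(square_mask(0, 0, 10), square_mask(5, 0, 10)) == pytest.approx(1 / 3)

    def test_zero_area_is_hard_error(self):
        degenerate = MaskRegion.from_raster(np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            iou(degenerate, square_mask(0, 0, 10))

    def test_matches_pixel_counting_on_random_shapes(self, rng):
        for _ in range(40):
            a = np.zeros((80, 80), bool)
            b = np.zeros((80, 80), bool)
            ax, ay = rng.integers(0, 40, 2)
            bx, by = rng.integers(0, 40, 2)
            a[ay:ay + rng.integers(5, 35), ax:ax + rng.integers(5, 35)] = True
            b[by:by + rng.integers(5, 35), bx:bx + rng.integers(5, 35)] = True
            ref = np.logical_and(a, b).sum() / np.logical_or(a, b).sum()
            got = iou(MaskRegion.from_raster(a), MaskRegion.from_raster(b))
            assert got == pytest.approx(ref)


class TestMatching:
    def test_perfect_predictions_all_matched(self):
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 20)),
               OrganInstance(Category.FLOWER, square_mask(100, 100, 30))]
        preds = [OrganInstance(g.category, g.mask, score=1.0) for g in gts]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        assert len(ms.pairs) == 2
        assert all(p.iou == 1.0 for p in ms.pairs)
        assert ms.unmatched_pred == [] and ms.unmatched_gt == []

    def test_higher_score_claims_contested_object(self):
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 20))]
        preds = [OrganInstance(Category.BUD, square_mask(1, 0, 20), score=0.6),
                 OrganInstance(Category.BUD, square_mask(0, 0, 20), score=0.9)]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        assert len(ms.pairs) == 1
        assert ms.pairs[0].pred_idx == 1
        assert ms.unmatched_pred == [0]

    def test_low_iou_prediction_unmatched(self):
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 10))]
        # IoU 1/3 < 0.5 -> no match
        preds = [OrganInstance(Category.BUD, square_mask(5, 0, 10), score=0.9)]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        assert ms.pairs == [] and ms.unmatched_pred == [0] and ms.unmatched_gt == [0]

    def test_mismatched_image_ids_raise(self):
        with pytest.raises(ValueError):
            match_instances(pred_sheet([], "a"), gt_sheet([], "b"))

    def test_equal_score_order_invariance(self):
        """The documented tie-break (input order) makes matching stable
        under permutation of equal-score predictions, up to relabeling."""
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 20)),
               OrganInstance(Category.BUD, square_mask(60, 0, 20))]
        p0 = OrganInstance(Category.BUD, square_mask(0, 0, 20), score=0.7)
        p1 = OrganInstance(Category.BUD, square_mask(60, 0, 20), score=0.7)
        ms_a = match_instances(pred_sheet([p0, p1]), gt_sheet(gts))
        ms_b = match_instances(pred_sheet([p1, p0]), gt_sheet(gts))
        pairs_a = {(id(ms_a.pred.instances[p.pred_idx]), p.gt_idx)
                   for p in ms_a.pairs}
        pairs_b = {(id(ms_b.pred.instances[p.pred_idx]), p.gt_idx)
                   for p in ms_b.pairs}
        assert pairs_a == pairs_b


class TestAveragePrecision:
    def test_perfect_retrieval(self):
        gts = [OrganInstance(Category.BUD, square_mask(i * 50, 0, 20))
               for i in range(4)]
        preds = [OrganInstance(g.category, g.mask, score=0.9) for g in gts]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        assert average_precision(ms, Category.BUD) == 1.0

    def test_hand_computed_sequence(self):
        """N_gt=3, ranked correctness [1,0,1] -> AP = (1 + 0 + 2/3)/3 = 5/9."""
        gts = [OrganInstance(Category.BUD, square_mask(i * 50, 0, 20))
               for i in range(3)]
        preds = [
            OrganInstance(Category.BUD, gts[0].mask, score=0.9),        # hit
            OrganInstance(Category.BUD, square_mask(300, 300, 20), score=0.8),  # miss
            OrganInstance(Category.BUD, gts[1].mask, score=0.7),        # hit
        ]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        assert average_precision(ms, Category.BUD) == pytest.approx(5 / 9)

    def test_no_predictions_gives_zero(self):
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 20))]
        ms = match_instances(pred_sheet([]), gt_sheet(gts))
        assert average_precision(ms, Category.BUD) == 0.0

    def test_no_ground_truth_is_undefined(self):
        ms = match_instances(pred_sheet([]), gt_sheet([]))
        assert average_precision(ms, Category.BUD) is None

    def test_matches_brute_force_on_random_suites(self, rng):
        """AP equals an explicit cumulative-precision loop on >=100
        random suites of <= 20 instances."""
        for _ in range(120):
            n_gt = int(rng.integers(1, 21))
            cats = [Category(int(c)) for c in rng.integers(1, 5, n_gt)]
            gts, preds, truth = [], [], []
            for i, cat in enumerate(cats):
                x = (i % 10) * 60
                y = (i // 10) * 60
                gts.append(OrganInstance(cat, square_mask(x, y, 20)))
                if rng.random() < 0.75:     # detected
                    dx = int(rng.integers(0, 4))
                    pcat = cat if rng.random() < 0.8 else \
                        Category(int(rng.integers(1, 5)))
                    preds.append(OrganInstance(
                        pcat, square_mask(x + dx, y, 20),
                        score=float(rng.random())))
                    truth.append((preds[-1], cat))
            for j in range(int(rng.integers(0, 5))):   # false alarms, far away
                pcat = Category(int(rng.integers(1, 5)))
                preds.append(OrganInstance(
                    pcat, square_mask(j * 60, 800, 20),
                    score=float(rng.random())))
                truth.append((preds[-1], None))
            ms = match_instances(pred_sheet(preds), gt_sheet(gts))
            truth_by_pred = {id(p): t for p, t in truth}
            for cat in Category:
                n = sum(1 for g in gts if g.category is cat)
                got = average_precision(ms, cat)
                if n == 0:
                    assert got is None
                    continue
                ranked = sorted((p for p in preds if p.category is cat),
                                key=lambda p: -p.score)
                total, correct = 0.0, 0
                for k, p in enumerate(ranked, start=1):
                    if truth_by_pred[id(p)] is cat:
                        correct += 1
                        total += correct / k
                assert got == pytest.approx(total / n)


class TestSizewiseAP:
    def test_all_small_found(self):
        gts = [OrganInstance(Category.BUD, square_mask(i * 50, 0, 30))
               for i in range(3)]
        preds = [OrganInstance(g.category, g.mask, score=0.9) for g in gts]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        sw = sizewise_ap(ms)
        assert sw == {"small": 1.0, "medium": None, "large": None}

    def test_65px_lands_in_medium(self):
        gts = [OrganInstance(Category.BUD, square_mask(0, 0, 65))]
        preds = [OrganInstance(Category.BUD, gts[0].mask, score=0.9)]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        sw = sizewise_ap(ms)
        assert sw["medium"] == 1.0 and sw["small"] is None

    def test_bins_partition_positive_sizes(self):
        for side in [1, 64, 65, 128, 129, 500]:
            assert sum(b.contains(side) for b in SIZE_BINS) == 1

    def test_subset_recompute_oracle(self, rng):
        """Per-bin AP equals a recomputation on the bin-filtered subset."""
        sides = [20, 30, 40, 70, 90, 100, 150, 200, 300]
        gts, preds = [], []
        for i, side in enumerate(sides):
            x = (i % 3) * 500
            y = (i // 3) * 500
            cat = Category(int(rng.integers(1, 5)))
            gts.append(OrganInstance(cat, square_mask(x, y, side)))
            if rng.random() < 0.8:
                preds.append(OrganInstance(cat, square_mask(x, y, side),
                                           score=float(rng.random())))
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        sw = sizewise_ap(ms)
        for b in SIZE_BINS:
            sub_gt = [g for g in gts if b.contains(g.mask.max_side)]
            sub_pred = [p for p in preds if b.contains(p.mask.max_side)]
            if not sub_gt:
                assert sw[b.name] is None
                continue
            ms_sub = match_instances(pred_sheet(sub_pred), gt_sheet(sub_gt))
            # pooled AP on the subset: rank all predictions together
            ranked = sorted(sub_pred, key=lambda p: -p.score)
            matched = {id(ms_sub.pred.instances[p.pred_idx]):
                       ms_sub.gt.instances[p.gt_idx].category
                       for p in ms_sub.pairs}
            total, correct = 0.0, 0
            for k, p in enumerate(ranked, start=1):
                if matched.get(id(p)) is p.category:
                    correct += 1
                    total += correct / k
            assert sw[b.name] == pytest.approx(total / len(sub_gt))


class TestCountingPrecision:
    @pytest.mark.parametrize("pred,true,expected", [
        (10, 10, 100.0), (12, 10, 120.0), (5, 10, 50.0)])
    def test_direction_convention(self, pred, true, expected):
        assert counting_precision(pred, true) == expected

    def test_zero_truth_absent(self):
        assert counting_precision(3, 0) is None

    def test_scale_invariance_under_sheet_duplication(self, small_sheet):
        from phenomask import PerturbationModel, perturb_predictions
        _, gt = small_sheet
        model = PerturbationModel(miss={c: 0.3 for c in Category}, seed=7)
        pred = perturb_predictions(gt, model)
        rep1 = evaluate_sheets([gt], [pred])
        gt2 = SheetAnnotation("s2", gt.width, gt.height, list(gt.instances),
                              gt.provenance)
        pred2 = SheetAnnotation("s2", gt.width, gt.height, list(pred.instances),
                                pred.provenance)
        rep2 = evaluate_sheets([gt, gt2], [pred, pred2])
        assert rep1.mean_cp() == pytest.approx(rep2.mean_cp())
        assert rep1.mean_mp() == pytest.approx(rep2.mean_mp())


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        gts = [OrganInstance(c, square_mask(50 * int(c), 0, 30))
               for c in Category]
        preds = [OrganInstance(g.category, g.mask, score=0.9) for g in gts]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        cm = confusion_matrix(ms)
        labels = [c.label for c in Category]
        assert np.allclose(cm.loc[labels, labels].to_numpy(), np.eye(4))
        assert np.allclose(cm["misdetection"], 0.0)

    def test_constructed_label_swap(self):
        gts = [OrganInstance(Category.FLOWER, square_mask(i * 50, 0, 30))
               for i in range(5)]
        preds = [OrganInstance(Category.BUD, g.mask, score=0.9) for g in gts]
        ms = match_instances(pred_sheet(preds), gt_sheet(gts))
        cm = confusion_matrix(ms)
        assert cm.loc["flower", "bud"] == 1.0
        assert cm.loc["flower", "flower"] == 0.0
        assert cm.loc["flower", "misdetection"] == 0.0
        assert np.isnan(cm.loc["bud", "bud"])   # no bud ground truth

    def test_rows_sum_to_at_most_one(self, small_sheet):
        from phenomask import PerturbationModel, perturb_predictions
        _, gt = small_sheet
        model = PerturbationModel(miss={c: 0.4 for c in Category}, seed=3)
        ms = match_instances(perturb_predictions(gt, model), gt)
        cm = confusion_matrix(ms)
        labels = [c.label for c in Category]
        sums = cm[labels].sum(axis=1).dropna()
        assert (sums <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(
            1.0 - sums, cm["misdetection"].dropna(), atol=1e-12)


class TestMeasurement:
    def test_diagonal_128px_square(self):
        m = square_mask(0, 0, 128)
        cm = instance_size_cm(m, ScaleCalibration())
        assert round(cm, 2) == 1.52

    def test_diagonal_64px_square(self):
        m = square_mask(0, 0, 64)
        assert round(instance_size_cm(m, ScaleCalibration()), 2) == 0.76

    def test_three_four_five_triangle(self):
        m = square_mask(0, 0, 1)
        m = MaskRegion.from_polygon([(0, 0), (30, 0), (30, 40), (0, 40)])
        assert instance_size_cm(m, ScaleCalibration(0.01)) == pytest.approx(0.5)

    def test_mp_identity_and_uniform_inflation(self):
        sizes = [1.0, 2.0, 3.0]
        assert measurement_precision(sizes, sizes) == 100.0
        assert measurement_precision(sizes, [s * 1.1 for s in sizes]) == \
            pytest.approx(110.0)

    def test_mp_empty_absent(self):
        assert measurement_precision([1.0], []) is None
        assert measurement_precision([], [1.0]) is None

    def test_statistics_quartiles(self):
        gts = [OrganInstance(Category.BUD, square_mask(i * 50, 0, 10 + i * 10))
               for i in range(4)]
        stats = measurement_statistics([gt_sheet(gts)], [pred_sheet([])])
        row = stats[(stats.category == "bud") &
                    (stats.source == "ground_truth")].iloc[0]
        sizes = sorted(np.hypot(s, s) * 0.0084 for s in [10, 20, 30, 40])
        assert row["n"] == 4
        assert row["median"] == pytest.approx(np.median(sizes))
        assert row["min"] == pytest.approx(sizes[0])
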