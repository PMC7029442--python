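"""Metric suite: confusion counts, Se/Sp/Acc/Pr/F1, Dice, ROC/AUC."""

import numpy as np
import pytest

from bscn.evaluate import (
    ConfusionCounts,
    confusion_counts,
    dice_from_masks,
    evaluate_dataset,
    metrics_from_counts,
    roc_auc,
)


def mann_whitney_auc(prob, gt):
    """Pairwise-comparison AUC oracle: P(score_pos > score_neg) + ties/2."""
    prob, gt = np.asarray(prob).ravel(), np.asarray(gt).ravel().astype(bool)
    pos, neg = prob[gt], prob[~gt]
    wins = ties = 0
    for p in pos:
        wins += int(np.sum(p > neg))
        ties += int(np.sum(p == neg))
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self, rng):
        gt = rng.random((20, 20)) < 0.3
        c = confusion_counts(gt, gt)
        assert c.FP == 0 and c.FN == 0
        assert c.TP == int(gt.sum())

    def test_inverted_prediction(self, rng):
        gt = rng.random((20, 20)) < 0.3
        c = confusion_counts(~gt, gt)
        assert c.TP == 0 and c.TN == 0

    def test_ten_pixel_toy_matches_loop_oracle(self):
        gt = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        c = confusion_counts(pred, gt)
        # independent per-pixel loop
        tp = fp = tn = fn = 0
        for p, g in zip(pred, gt):
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and not g:
                tn += 1
            else:
                fn += 1
        assert (c.TP, c.FP, c.TN, c.FN) == (tp, fp, tn, fn) == (3, 1, 5, 1)

    def test_mask_restricts_counting(self, rng):
        gt = rng.random((10, 10)) < 0.5
        pred = rng.random((10, 10)) < 0.5
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        c = confusion_counts(pred, gt, mask)
        assert c.total == 50

    def test_counts_sum_to_pixels(self, rng):
        gt = rng.random((13, 7)) < 0.4
        pred = rng.random((13, 7)) < 0.4
        assert confusion_counts(pred, gt).total == 13 * 7

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([0.5, 1.0]), np.array([0.0, 1.0]))


class TestMetricsFromCounts:
    def test_hand_evaluated_toy(self):
        se, sp, acc, pr, f1 = metrics_from_counts(ConfusionCounts(3, 1, 5, 1))
        assert se == pytest.approx(0.75)
        assert sp == pytest.approx(5 / 6)
        assert acc == pytest.approx(0.8)
        assert pr == pytest.approx(0.75)
        assert f1 == pytest.approx(0.75)

    def test_perfect_counts_all_ones(self):
        assert metrics_from_counts(ConfusionCounts(5, 0, 5, 0)) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_tp_with_fn_gives_zero_sensitivity(self):
        se, *_ = metrics_from_counts(ConfusionCounts(0, 2, 5, 3))
        assert se == 0.0

    def test_zero_over_zero_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            se, *_ = metrics_from_counts(ConfusionCounts(0, 0, 5, 0))
        assert se == 0.0


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((15, 15)) < 0.4
        assert dice_from_masks(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_from_masks(a, b) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=bool)
        assert dice_from_masks(z, z) == 1.0

    def test_dice_equals_f1_on_random_masks(self, rng):
        """Algebraic identity Dice == F1, checked numerically."""
        for _ in range(1000):
            gt = rng.random((8, 8)) < rng.uniform(0.1, 0.9)
            pred = rng.random((8, 8)) < rng.uniform(0.1, 0.9)
            if not (gt.any() or pred.any()):
                continue
            c = confusion_counts(pred, gt)
            if c.TP + c.FN == 0 or c.TP + c.FP == 0:
                continue
            *_, f1 = metrics_from_counts(c)
            assert dice_from_masks(gt, pred) == pytest.approx(f1, abs=1e-12)


class TestRocAuc:
    def test_perfect_probabilities(self, rng):
        gt = rng.random((10, 10)) < 0.3
        _, auc = roc_auc(gt.astype(float), gt)
        assert auc == 1.0

    def test_inverted_probabilities(self, rng):
        gt = rng.random((10, 10)) < 0.3
        _, auc = roc_auc(1.0 - gt.astype(float), gt)
        assert auc == 0.0

    @pytest.mark.parametrize("n", [20, 200, 2000])
    def test_matches_mann_whitney_oracle(self, n, rng):
        gt = rng.random(n) < 0.4
        if not gt.any() or gt.all():
            gt[0], gt[-1] = True, False
        prob = np.round(rng.random(n), 2)  # coarse grid forces ties
        _, auc = roc_auc(prob, gt)
        assert auc == pytest.approx(mann_whitney_auc(prob, gt), abs=1e-12)

    def test_single_class_gt_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.random.default_rng(0).random(10), np.ones(10, dtype=bool))

    def test_permutation_invariance(self, rng):
        gt = rng.random(100) < 0.3
        gt[:2] = [True, False]
        prob = rng.random(100)
        perm = rng.permutation(100)
        _, a = roc_auc(prob, gt)
        _, b = roc_auc(prob[perm], gt[perm])
        assert a == pytest.approx(b, abs=1e-12)


class TestEvaluateDataset:
    @pytest.fixture()
    def dataset(self, tmp_path, rng):
        pred_dir = tmp_path / "pred"
        gt_dir = tmp_path / "gt"
        pred_dir.mkdir()
        gt_dir.mkdir()
        import imageio.v3 as iio

        truths, probs = {}, {}
        for stem in ("a", "b", "c"):
            gt = rng.random((24, 24)) < 0.3
            prob = np.clip(gt * 0.7 + rng.random((24, 24)) * 0.3, 0, 1)
            np.save(pred_dir / f"{stem}.npy", prob)
            iio.imwrite(gt_dir / f"{stem}.png",
                        (gt * 255).astype(np.uint8))
            truths[stem], probs[stem] = gt, prob
        return pred_dir, gt_dir, truths, probs

    def test_single_image_aggregate_equals_row(self, tmp_path, rng):
        import imageio.v3 as iio

        pred_dir, gt_dir = tmp_path / "p", tmp_path / "g"
        pred_dir.mkdir(), gt_dir.mkdir()
        gt = rng.random((16, 16)) < 0.4
        prob = rng.random((16, 16))
        np.save(pred_dir / "only.npy", prob)
        iio.imwrite(gt_dir / "only.png", (gt * 255).astype(np.uint8))
        reports, aggregate, _ = evaluate_dataset(pred_dir, gt_dir)
        r = reports[0]
        for attr in ("Se", "Sp", "Acc", "Pr", "F1", "Dice", "AUC"):
            assert getattr(aggregate, attr) == pytest.approx(
                getattr(r, attr), abs=1e-12)

    def test_pooled_aggregation_matches_concatenation_oracle(self, dataset):
        pred_dir, gt_dir, truths, probs = dataset
        _, aggregate, _ = evaluate_dataset(pred_dir, gt_dir, threshold=0.5)
        gt_all = np.concatenate([truths[s].ravel() for s in ("a", "b", "c")])
        prob_all = np.concatenate([probs[s].ravel() for s in ("a", "b", "c")])
        c = confusion_counts(prob_all >= 0.5, gt_all)
        se, sp, acc, pr, f1 = metrics_from_counts(c)
        assert aggregate.Se == pytest.approx(se, abs=1e-12)
        assert aggregate.Acc == pytest.approx(acc, abs=1e-12)
        assert aggregate.AUC == pytest.approx(
            mann_whitney_auc(prob_all, gt_all), abs=1e-9)

    def test_unmatched_ids_skipped_with_warning(self, dataset, tmp_path, rng):
        pred_dir, gt_dir, _, _ = dataset
        np.save(pred_dir / "orphan.npy", rng.random((24, 24)))
        with pytest.warns(UserWarning, match="orphan"):
            reports, _, skipped = evaluate_dataset(pred_dir, gt_dir)
        assert "orphan" in skipped and len(reports) == 3

    def test_empty_intersection_returns_no_aggregate(self, tmp_path, rng):
        pred_dir, gt_dir = tmp_path / "p", tmp_path / "g"
        pred_dir.mkdir(), gt_dir.mkdir()
        np.save(pred_dir / "x.npy", rng.random((8, 8)))
        with pytest.warns(UserWarning):
            reports, aggregate, skipped = evaluate_dataset(pred_dir, gt_dir)
        assert reports == [] and aggregate is None and skipped == ["x"]

    def test_writes_csv_and_json(self, dataset, tmp_path):
        pred_dir, gt_dir, _, _ = dataset
        out = tmp_path / "report"
        evaluate_dataset(pred_dir, gt_dir, out_dir=out)
        assert (out / "metrics.csv").exists()
        import json

        blob = json.loads((out / "metrics.json").read_text())
        assert blob["aggregate"]["image_id"] == "aggregate"
        assert len(blob["per_image"]) == 3
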