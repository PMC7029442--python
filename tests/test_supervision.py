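"""Cascade supervision targets, class-balanced loss, degeneracy diagnostic."""

import numpy as np
import pytest

from bscn import nn
from bscn.network import CascadeOutput
from bscn.supervision import (
    LossConfig,
    balanced_bce,
    build_targets,
    cascade_gradient_discrepancy,
    naive_gradient_degeneracy,
    total_loss,
)


def _random_setup(rng, D=5, shape=(6, 6)):
    Y = (rng.random(shape) < 0.3).astype(float)
    l2h = [rng.uniform(0.05, 0.95, shape) for _ in range(D)]
    h2l = [rng.uniform(0.05, 0.95, shape) for _ in range(D)]
    return Y, l2h, h2l


def bce_oracle(pred, target, eta, lam):
    """Independent elementwise-loop evaluation of the balanced BCE."""
    pred = np.clip(np.asarray(pred, float).ravel(), 1e-7, 1 - 1e-7)
    target = np.asarray(target, float).ravel()
    pos = [i for i in range(len(target)) if target[i] > eta]
    neg = [i for i in range(len(target)) if target[i] == 0]
    n = len(pos) + len(neg)
    if n == 0:
        return 0.0
    beta = len(neg) / n
    one_minus_beta = lam * len(pos) / n
    s = -beta * sum(np.log(pred[i]) for i in pos)
    s -= one_minus_beta * sum(np.log(1 - pred[i]) for i in neg)
    return s / target.size


class TestBuildTargets:
    def test_first_stage_l2h_is_label(self, rng):
        Y, l2h, h2l = _random_setup(rng)
        pairs = build_targets(Y, l2h, h2l)
        np.testing.assert_array_equal(pairs[0].y_l2h, Y)

    def test_last_stage_h2l_is_label(self, rng):
        Y, l2h, h2l = _random_setup(rng)
        pairs = build_targets(Y, l2h, h2l)
        np.testing.assert_array_equal(pairs[-1].y_h2l, Y)

    def test_preclamp_sum_identity(self, rng):
        """Pre-clamp, y_l2h(d)+y_h2l(d) = 2Y - sum_{i<d}P_l2h - sum_{i>d}P_h2l."""
        for _ in range(1000):
            Y, l2h, h2l = _random_setup(rng, D=3, shape=(4, 4))
            pairs = build_targets(Y, l2h, h2l, clamp=False)
            for d, pair in enumerate(pairs, start=1):
                expected = (2 * Y
                            - sum(l2h[i] for i in range(d - 1))
                            - sum(h2l[i] for i in range(d, 3)))
                np.testing.assert_allclose(pair.y_l2h + pair.y_h2l, expected,
                                           atol=1e-12)

    def test_targets_clamped_to_unit_interval(self, rng):
        Y, l2h, h2l = _random_setup(rng)
        for pair in build_targets(Y, l2h, h2l):
            for t in (pair.y_l2h, pair.y_h2l):
                assert t.min() >= 0.0 and t.max() <= 1.0

    def test_dimension_mismatch_rejected(self, rng):
        Y = np.zeros((4, 4))
        with pytest.raises(ValueError):
            build_targets(Y, [np.zeros((3, 3))], [np.zeros((4, 4))])

    def test_targets_are_constants_no_gradient_flow(self, rng):
        """Gradients must not flow through the targets: the gradient of the
        stage-d loss w.r.t. a *different* stage's map is zero."""
        Y = (rng.random((5, 5)) < 0.3).astype(float)
        logits = [nn.Tensor(rng.standard_normal((5, 5)), requires_grad=True)
                  for _ in range(3)]
        probs = [nn.sigmoid(t) for t in logits]
        pairs = build_targets(Y, probs, probs)
        loss = nn.balanced_bce_op(probs[2], pairs[2].y_l2h)
        loss.backward()
        # stage-3 l2h target depends on stages 1,2 numerically, but they are
        # frozen: no gradient may reach them through the target
        assert logits[0].grad is None or np.all(logits[0].grad == 0)
        assert logits[2].grad is not None and np.any(logits[2].grad != 0)


class TestBalancedBCE:
    def test_perfect_negative_prediction_loss_vanishes(self):
        target = np.zeros((4, 4))
        pred = np.full((4, 4), 1e-9)
        assert balanced_bce(pred, target) < 1e-6

    def test_mid_band_pixels_have_no_influence(self, rng):
        target = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.2])
        pred = np.array([0.9, 0.8, 0.1, 0.2, 0.3, 0.5])
        base = balanced_bce(pred, target, eta=0.4)
        for v in (0.01, 0.5, 0.99):
            pert = pred.copy()
            pert[5] = v
            assert balanced_bce(pert, target, eta=0.4) == pytest.approx(base)

    def test_six_pixel_toy_matches_loop_oracle(self):
        target = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.2])
        pred = np.array([0.9, 0.8, 0.1, 0.2, 0.3, 0.5])
        got = balanced_bce(pred, target, eta=0.4, lam=1.1)
        assert got == pytest.approx(bce_oracle(pred, target, 0.4, 1.1),
                                    rel=1e-12)

    def test_random_maps_match_loop_oracle(self, rng):
        for _ in range(50):
            target = np.where(rng.random((5, 5)) < 0.4,
                              rng.choice([0.0, 0.3, 1.0], size=(5, 5)), 0.0)
            pred = rng.uniform(0.01, 0.99, (5, 5))
            got = balanced_bce(pred, target)
            assert got == pytest.approx(bce_oracle(pred, target, 0.4, 1.1),
                                        rel=1e-10)

    def test_nonnegative_and_to_zero_at_targets(self, rng):
        target = (rng.random((8, 8)) < 0.3).astype(float)
        pred = np.clip(target, 1e-8, 1 - 1e-8)
        assert balanced_bce(pred, target) < 1e-6
        assert balanced_bce(rng.uniform(0.01, 0.99, (8, 8)), target) >= 0

    def test_empty_classes_warns_and_returns_zero(self):
        target = np.full((3, 3), 0.2)  # everything in the excluded band
        with pytest.warns(UserWarning):
            assert balanced_bce(np.full((3, 3), 0.5), target) == 0.0

    def test_lambda_scales_negative_weight_exactly(self, rng):
        """Only the negative-class term changes, by exactly the ratio."""
        target = (rng.random((6, 6)) < 0.4).astype(float)
        pred = rng.uniform(0.1, 0.9, (6, 6))
        pos_term = bce_oracle(pred, target, 0.4, 0.0)  # lam=0 kills negatives
        l10 = balanced_bce(pred, target, lam=1.0)
        l11 = balanced_bce(pred, target, lam=1.1)
        neg10, neg11 = l10 - pos_term, l11 - pos_term
        assert neg11 == pytest.approx(1.1 * neg10, rel=1e-9)


class TestTotalLoss:
    def _toy_output(self, rng, D=2, shape=(4, 4)):
        Y = (rng.random(shape) < 0.4).astype(float)
        out = CascadeOutput(
            side_l2h=[rng.uniform(0.05, 0.95, shape) for _ in range(D)],
            side_h2l=[rng.uniform(0.05, 0.95, shape) for _ in range(D)],
            fused=rng.uniform(0.05, 0.95, shape),
        )
        pairs = build_targets(Y, out.side_l2h, out.side_h2l)
        return Y, out, pairs

    def test_zero_side_weight_leaves_fusion_only(self, rng):
        Y, out, pairs = self._toy_output(rng)
        cfg = LossConfig(w_side=0.0, w_fuse=1.2)
        total, bd = total_loss(out, pairs, Y, cfg)
        assert total == pytest.approx(1.2 * bd["fuse"])

    def test_linear_in_weights(self, rng):
        Y, out, pairs = self._toy_output(rng)
        t11, _ = total_loss(out, pairs, Y, LossConfig(w_side=1.0, w_fuse=1.0))
        t20, _ = total_loss(out, pairs, Y, LossConfig(w_side=2.0, w_fuse=0.0))
        t02, _ = total_loss(out, pairs, Y, LossConfig(w_side=0.0, w_fuse=2.0))
        assert t11 == pytest.approx((t20 + t02) / 2, rel=1e-12)

    def test_matches_from_scratch_summation(self, rng):
        """Full side + fusion loss vs an independent loop over Eqs. of the
        weighted side/fusion decomposition."""
        Y, out, pairs = self._toy_output(rng, D=3)
        cfg = LossConfig()
        total, _ = total_loss(out, pairs, Y, cfg)
        expected = 0.0
        for d in range(3):
            expected += bce_oracle(out.side_l2h[d], pairs[d].y_l2h, 0.4, 1.1)
            expected += bce_oracle(out.side_h2l[d], pairs[d].y_h2l, 0.4, 1.1)
        expected *= cfg.w_side
        expected += cfg.w_fuse * bce_oracle(out.fused, Y, 0.4, 1.1)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_l1_fusion_option(self, rng):
        Y, out, pairs = self._toy_output(rng)
        cfg = LossConfig(w_side=0.0, w_fuse=1.0, fusion_loss="l1")
        total, _ = total_loss(out, pairs, Y, cfg)
        assert total == pytest.approx(np.abs(out.fused - Y).mean())


class TestGradientDegeneracy:
    def test_naive_supervision_gradients_identical(self, rng):
        Y = (rng.random((6, 6)) < 0.3).astype(float)
        preds = [rng.uniform(0.02, 0.15, (6, 6)) for _ in range(5)]
        assert naive_gradient_degeneracy(preds, Y) < 1e-6

    def test_l1_two_stage_case_exactly_degenerate(self, rng):
        Y = (rng.random((5, 5)) < 0.4).astype(float)
        preds = [rng.uniform(0.1, 0.4, (5, 5)) for _ in range(2)]
        assert naive_gradient_degeneracy(preds, Y, loss="l1") == 0.0

    def test_bidirectional_targets_break_degeneracy(self, rng):
        Y = (rng.random((6, 6)) < 0.3).astype(float)
        preds = [rng.uniform(0.2, 0.8, (6, 6)) for _ in range(5)]
        assert cascade_gradient_discrepancy(preds, Y) > 1e-3

    def test_single_stage_rejected(self, rng):
        with pytest.raises(ValueError):
            naive_gradient_degeneracy([np.zeros((3, 3))], np.zeros((3, 3)))
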