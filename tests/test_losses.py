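"""Combo loss, simplified loss, and Dice metric contracts."""

import math

import numpy as np
import pytest

from simlabel.errors import DataError, DimensionError
from simlabel.grouping import build_matrix, identity_grouping
from simlabel.losses import (
    LossConfig,
    combo_loss,
    mean_dice,
    per_class_dice,
    simplified_loss,
)
from simlabel.nn.tensor import Tensor


def _random_prob_map(rng, b, n, h, w):
    logits = rng.normal(size=(b, n, h, w))
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return (e / e.sum(axis=1, keepdims=True)).astype(np.float32)


class TestComboLoss:
    def test_perfect_prediction_approaches_minus_half(self):
        """mCE -> 0 and DSC -> 1, so L -> -(1 - alpha) = -0.5."""
        target = np.array([[[0, 1], [1, 0]]])
        pred = np.eye(2, dtype=np.float32)[target].transpose(0, 3, 1, 2)
        val = combo_loss(pred, target).item()
        assert val == pytest.approx(-0.5, abs=1e-4)

    def test_uniform_two_class_single_pixel_hand_computed(self):
        """Term-by-term arithmetic for p=[.5,.5], t=[1,0], alpha=beta=0.5."""
        pred = np.array([0.5, 0.5], dtype=np.float32).reshape(1, 2, 1, 1)
        target = np.zeros((1, 1, 1), dtype=np.int64)
        cfg = LossConfig(alpha=0.5, beta=0.5, eps=1e-6)
        # modified CE: -(0.5*1*ln .5 + 0.5*0*ln .5 + 0.5*0*ln .5 + 0.5*1*ln .5)
        m_ce = -(0.5 * math.log(0.5) + 0.5 * math.log(0.5))
        # Dice: class0 (2*0.5+eps)/(0.5+1+eps); class1 (0+eps)/(0.5+0+eps)
        dsc = ((1.0 + cfg.eps) / (1.5 + cfg.eps) + cfg.eps / (0.5 + cfg.eps)) / 2
        expected = 0.5 * m_ce - 0.5 * dsc
        assert combo_loss(pred, target, cfg).item() == pytest.approx(expected, rel=1e-5)

    def test_permutation_invariant_to_pixel_order(self):
        rng = np.random.default_rng(0)
        pred = _random_prob_map(rng, 1, 3, 4, 4)
        target = rng.integers(0, 3, (1, 4, 4))
        perm = rng.permutation(16)
        pred_p = pred.reshape(1, 3, 16)[:, :, perm].reshape(1, 3, 4, 4)
        target_p = target.reshape(1, 16)[:, perm].reshape(1, 4, 4)
        a = combo_loss(pred, target).item()
        b = combo_loss(pred_p, target_p).item()
        assert a == pytest.approx(b, rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(DimensionError):
            combo_loss(np.ones((1, 2, 4, 4), dtype=np.float32) / 2,
                       np.zeros((1, 3, 3), dtype=np.int64))

    def test_out_of_range_probabilities_rejected(self):
        bad = np.full((1, 2, 2, 2), 1.5, dtype=np.float32)
        with pytest.raises(DataError, match="probabilities"):
            combo_loss(bad, np.zeros((1, 2, 2), dtype=np.int64))


class TestSimplifiedLoss:
    def test_identity_matrix_is_bit_identical_to_combo(self):
        """With M = I, group-level training reduces exactly to strong-label
        training: the losses agree bit for bit."""
        rng = np.random.default_rng(1)
        I5 = build_matrix(identity_grouping([f"c{i}" for i in range(5)]))
        for _ in range(20):
            pred = _random_prob_map(rng, 2, 5, 6, 6)
            target = rng.integers(0, 5, (2, 6, 6))
            a = simplified_loss(pred, target, I5).item()
            b = combo_loss(pred, target).item()
            assert a == b  # exact equality, no tolerance

    def test_within_group_symmetry(self, table_grouping):
        """Mass on liver or on gallbladder is indistinguishable when the
        target is the organ group."""
        M = build_matrix(table_grouping)
        liver = table_grouping.classes.index("liver")
        gall = table_grouping.classes.index("gallbladder")
        organ = table_grouping.groups.index("organ")
        target = np.full((1, 2, 2), organ, dtype=np.int64)

        def concentrated(idx):
            p = np.full((1, 8, 2, 2), 0.01, dtype=np.float32)
            p[:, idx] = 1.0 - 0.07
            return p

        a = simplified_loss(concentrated(liver), target, M).item()
        b = simplified_loss(concentrated(gall), target, M).item()
        assert a == pytest.approx(b, rel=1e-6)

    def test_matches_pixel_loop_materialization(self, table_grouping):
        M = build_matrix(table_grouping)
        rng = np.random.default_rng(2)
        pred = _random_prob_map(rng, 1, 8, 3, 3)
        target = rng.integers(0, 4, (1, 3, 3))
        grouped = np.empty((1, 4, 3, 3), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                grouped[0, :, i, j] = (M.entries @ pred[0, :, i, j]).astype(np.float32)
        a = simplified_loss(pred, target, M).item()
        b = combo_loss(grouped, target).item()
        assert a == pytest.approx(b, rel=1e-6)

    def test_gradient_flows_through_projection(self, table_grouping):
        M = build_matrix(table_grouping)
        rng = np.random.default_rng(3)
        pred = Tensor(_random_prob_map(rng, 1, 8, 4, 4), requires_grad=True)
        loss = simplified_loss(pred, rng.integers(0, 4, (1, 4, 4)), M)
        loss.backward()
        assert pred.grad is not None and np.abs(pred.grad).max() > 0

    def test_dimension_mismatches_name_the_axis(self, table_grouping):
        M = build_matrix(table_grouping)
        with pytest.raises(DimensionError, match="class axis"):
            simplified_loss(np.ones((1, 5, 2, 2), dtype=np.float32) / 5,
                            np.zeros((1, 2, 2), dtype=np.int64), M)
        with pytest.raises(DimensionError, match="group axis"):
            simplified_loss(np.ones((1, 8, 2, 2), dtype=np.float32) / 8,
                            np.full((1, 2, 2), 6, dtype=np.int64), M)


def _brute_force_dice(pred, target, n):
    """Set-count oracle: Dice from explicit pixel-coordinate sets."""
    out = []
    coords = [(i, j) for i in range(pred.shape[0]) for j in range(pred.shape[1])]
    for c in range(n):
        P = {xy for xy in coords if pred[xy] == c}
        T = {xy for xy in coords if target[xy] == c}
        if not P and not T:
            out.append(1.0)
        else:
            out.append(2 * len(P & T) / (len(P) + len(T)))
    return np.array(out)


class TestDice:
    def test_perfect_prediction_scores_one(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 4, (5, 5))
        res = per_class_dice(t, t, 4)
        assert (res.per_class == 1.0).all()
        assert res.mean == 1.0

    def test_two_one_overlap_example(self):
        """|P|=2, |T|=1, overlap 1 -> Dice = 2/3."""
        pred = np.zeros((2, 2), dtype=np.int64)
        pred[0, 0] = pred[0, 1] = 1
        target = np.zeros((2, 2), dtype=np.int64)
        target[0, 0] = 1
        res = per_class_dice(pred, target, 2)
        assert res.per_class[1] == pytest.approx(2 / 3)

    def test_symmetric_in_pred_and_target(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, (6, 6))
        b = rng.integers(0, 3, (6, 6))
        np.testing.assert_allclose(
            per_class_dice(a, b, 3).per_class, per_class_dice(b, a, 3).per_class
        )

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            pred = rng.integers(0, n, (5, 4))
            target = rng.integers(0, n, (5, 4))
            np.testing.assert_allclose(
                per_class_dice(pred, target, n).per_class,
                _brute_force_dice(pred, target, n),
            )

    def test_absent_class_scores_one_and_is_flagged(self):
        pred = np.zeros((3, 3), dtype=np.int64)
        target = np.zeros((3, 3), dtype=np.int64)
        res = per_class_dice(pred, target, 3)
        assert res.per_class[1] == 1.0 and res.absent[1]
        assert not res.absent[0]

    def test_monotone_under_added_errors(self):
        """Dice never increases as disjoint wrong pixels are added."""
        target = np.zeros((4, 4), dtype=np.int64)
        target[:2] = 1
        pred = target.copy()
        last = mean_dice(pred, target, 2)
        for (i, j) in [(3, 0), (3, 1), (3, 2)]:
            pred[i, j] = 1  # wrong: target there is 0
            cur = mean_dice(pred, target, 2)
            assert cur <= last + 1e-12
            last = cur

    def test_n_classes_too_small_rejected(self):
        with pytest.raises(DataError):
            per_class_dice(np.array([[5]]), np.array([[0]]), 3)

    def test_counts_pool_over_the_whole_set(self):
        """Micro aggregation: two maps together differ from per-image mean."""
        pred = [np.array([[1, 1]]), np.array([[0, 0]])]
        target = [np.array([[1, 0]]), np.array([[0, 0]])]
        pooled = per_class_dice(pred, target, 2)
        per_img = per_class_dice(pred, target, 2, per_image=True)
        # class 1: pooled 2*1/(2+1); per-image mean of 2/3 and 1.0
        assert pooled.per_class[1] == pytest.approx(2 / 3)
        assert per_img.per_class[1] == pytest.approx((2 / 3 + 1.0) / 2)
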