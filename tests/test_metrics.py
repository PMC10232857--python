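"""Losses, ability scores, ratio accounting and evaluation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fedmsrw as fm
from fedmsrw.metrics import ConfusionCounts, confusion_counts


def _rand_pair(rng, shape=(8, 8, 8), p_lesion=0.2):
    pred = rng.random(shape)
    target = (rng.random(shape) < p_lesion).astype(float)
    return pred, target


class TestSoftDice:
    def test_perfect_binary_prediction_is_exact_zero(self):
        y = np.zeros((4, 4, 4))
        y[:2] = 1.0
        assert fm.soft_dice_loss(y, y) == 0.0

    def test_total_miss_is_close_to_one(self):
        y = np.zeros((4, 4, 4))
        y[0, 0, :2] = 1.0
        assert fm.soft_dice_loss(np.zeros_like(y), y) == pytest.approx(1.0, abs=1e-4)

    def test_half_probability_hand_value(self):
        # uniform 0.5 over 8 voxels, 4 true: 1 - (2*2)/(2+4) = 1/3
        pred = np.full(8, 0.5)
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        assert fm.soft_dice_loss(pred, target) == pytest.approx(1 / 3, abs=1e-5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            fm.soft_dice_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_matches_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pred, target = _rand_pair(rng)
            num = 2 * math.fsum((pred * target).ravel()) + 1e-5
            den = (
                math.fsum((pred**2).ravel())
                + math.fsum((target**2).ravel())
                + 1e-5
            )
            assert fm.soft_dice_loss(pred, target) == pytest.approx(
                1 - num / den, abs=1e-6
            )

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        pred, target = _rand_pair(rng, shape=(4, 4, 4))
        grad = fm.soft_dice_loss_grad(pred, target)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            p = pred.copy()
            p[idx] += eps
            up = fm.soft_dice_loss(p, target)
            p[idx] -= 2 * eps
            down = fm.soft_dice_loss(p, target)
            assert grad[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_and_permutation_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        pred, target = _rand_pair(rng, shape=(6, 6, 6))
        loss = fm.soft_dice_loss(pred, target)
        assert 0.0 <= loss <= 1.0
        perm = rng.permutation(pred.size)
        assert fm.soft_dice_loss(
            pred.ravel()[perm], target.ravel()[perm]
        ) == pytest.approx(loss, abs=1e-12)


class TestSegmentationAbility:
    def test_perfect_prediction_scores_one(self):
        y = np.zeros((4, 4, 4))
        y[1, 1, 1] = 1.0
        obs = fm.segmentation_ability(y, y)
        assert obs.present and obs.value == pytest.approx(1.0)

    def test_empty_ground_truth_is_absent(self):
        obs = fm.segmentation_ability(np.full((4, 4, 4), 0.3), np.zeros((4, 4, 4)))
        assert not obs.present
        assert obs.reason_absent == "empty_ground_truth"

    def test_half_probability_hand_value(self):
        pred = np.full(8, 0.5)
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        # confidence 0.5 times (1 - 1/3)
        assert fm.segmentation_ability(pred, target).value == pytest.approx(
            0.5 * (2 / 3), abs=1e-5
        )

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pred, target = _rand_pair(rng)
            obs = fm.segmentation_ability(pred, target)
            conf = math.fsum((pred * target).ravel()) / math.fsum(target.ravel())
            expect = conf * (1 - fm.soft_dice_loss(pred, target))
            assert obs.value == pytest.approx(expect, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_true_lesion_confidence(self, seed):
        """Raising pred on true-lesion voxels never lowers the ability."""
        rng = np.random.default_rng(seed)
        pred, target = _rand_pair(rng, shape=(6, 6, 6), p_lesion=0.3)
        base = fm.segmentation_ability(pred, target).value
        raised = np.where(target > 0, pred + 0.5 * (1 - pred), pred)
        assert fm.segmentation_ability(raised, target).value >= base - 1e-12


class TestEntropyAbility:
    def test_confident_predictions_have_zero_entropy(self):
        y = np.zeros((4, 4, 4))
        y[0] = 1.0
        assert fm.entropy_ability(np.zeros_like(y), y) == pytest.approx(0.0)
        assert fm.entropy_ability(np.ones_like(y), y) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_half_hand_value(self):
        pred = np.full((4, 4, 4), 0.5)
        y = np.zeros((4, 4, 4))
        y[0] = 1.0
        loss = fm.soft_dice_loss(pred, y)
        assert fm.entropy_ability(pred, y) == pytest.approx(
            0.5 * math.log(2) * (1 - loss), abs=1e-9
        )

    def test_scales_down_with_worse_dice(self):
        pred = np.full((4, 4, 4), 0.5)
        small = np.zeros((4, 4, 4))
        small[0, 0, 0] = 1.0
        big = np.zeros((4, 4, 4))
        big[:2] = 1.0
        # big target overlaps more with the uniform prediction -> lower loss
        assert fm.soft_dice_loss(pred, big) < fm.soft_dice_loss(pred, small)
        assert fm.entropy_ability(pred, big) > fm.entropy_ability(pred, small)


class TestLesionVolumeRatio:
    def test_direct_count(self):
        vol = np.zeros((5, 5, 5))
        vol.ravel()[:100] = 10.0
        msk = np.zeros((5, 5, 5), dtype=bool)
        msk.ravel()[0] = True
        assert fm.lesion_volume_ratio(vol, msk) == pytest.approx(0.01)

    def test_empty_mask_and_empty_brain(self):
        vol = np.ones((3, 3, 3))
        assert fm.lesion_volume_ratio(vol, np.zeros_like(vol)) == 0.0
        assert fm.lesion_volume_ratio(np.zeros_like(vol), np.ones_like(vol)) == 0.0


class TestRunningRatio:
    def test_running_mean_by_hand(self):
        state = fm.ClientState()
        state = fm.update_running_ratio(state, 0.02)
        assert state.vr == pytest.approx(0.02)
        state = fm.update_running_ratio(state, 0.04)
        assert state.vr == pytest.approx(0.03)
        assert state.rounds_seen == 2

    def test_fixed_point_and_negative_rejected(self):
        state = fm.ClientState(vr=0.05, rounds_seen=3)
        assert fm.update_running_ratio(state, 0.05).vr == pytest.approx(0.05)
        with pytest.raises(ValueError):
            fm.update_running_ratio(state, -0.1)

    def test_equals_mean_of_round_means(self):
        rng = np.random.default_rng(3)
        means = rng.random(17) * 0.1
        state = fm.ClientState()
        for m in means:
            state = fm.update_running_ratio(state, float(m))
        assert state.vr == pytest.approx(float(np.mean(means)), abs=1e-12)


class TestVolumeMetrics:
    def test_hand_values(self):
        dice, tpr, fpr = fm.volume_metrics(ConfusionCounts(tp=10, fp=5, fn=5))
        assert dice == pytest.approx(2 / 3, abs=1e-4)
        assert tpr == pytest.approx(2 / 3, abs=1e-4)
        assert fpr == pytest.approx(1 / 3, abs=1e-4)

    def test_degenerate_conventions(self):
        assert fm.volume_metrics(ConfusionCounts(5, 0, 0)) == (1.0, 1.0, 0.0)
        assert fm.volume_metrics(ConfusionCounts(0, 0, 0)) == (1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)

    def test_agrees_with_voxel_by_voxel_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            pred = rng.random((8, 8, 8)) < 0.3
            true = rng.random((8, 8, 8)) < 0.3
            c = confusion_counts(pred, true)
            tp = fp = fn = 0
            for p, t in zip(pred.ravel(), true.ravel()):
                tp += p and t
                fp += p and not t
                fn += t and not p
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
            dice, tpr, fpr = fm.volume_metrics(c)
            assert dice == (2 * tp / (fn + 2 * tp + fp) if tp + fp + fn else 1.0)
            assert tpr == (tp / (tp + fn) if tp + fn else 1.0)
            assert fpr == (fp / (tp + fp) if tp + fp else 0.0)


class TestEvaluateCases:
    def test_single_case_c_equals_v(self):
        rng = np.random.default_rng(5)
        pred = {"a": rng.random((6, 6, 6)) < 0.2}
        true = {"a": rng.random((6, 6, 6)) < 0.2}
        rep = fm.evaluate_cases(pred, true)
        assert rep.c_dice == pytest.approx(rep.v_dice)

    def test_pooled_vs_averaged_hand_example(self):
        # case 1: perfect (2 lesion voxels); case 2: complete miss (1 voxel)
        t1 = np.zeros((3, 3, 3), dtype=bool)
        t1[0, 0, :2] = True
        t2 = np.zeros((3, 3, 3), dtype=bool)
        t2[1, 1, 1] = True
        preds = {"c1": t1.copy(), "c2": np.zeros_like(t2)}
        rep = fm.evaluate_cases(preds, {"c1": t1, "c2": t2})
        assert rep.c_dice == pytest.approx(50.0)
        # pooled: TP=2, FN=1, FP=0 -> 2*2/(1+4) = 80%
        assert rep.v_dice == pytest.approx(80.0)

    def test_perfect_predictions_report_in_percent(self):
        t = np.zeros((4, 4, 4), dtype=bool)
        t[1] = True
        rep = fm.evaluate_cases({"x": t.copy()}, {"x": t})
        assert (rep.c_dice, rep.v_dice, rep.v_tpr, rep.v_fpr) == (100, 100, 100, 0)

    def test_shape_mismatch_names_the_case(self):
        with pytest.raises(ValueError, match="bad"):
            fm.evaluate_cases(
                {"bad": np.zeros((2, 2, 2), dtype=bool)},
                {"bad": np.zeros((3, 3, 3), dtype=bool)},
            )
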