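"""Overlap metrics and the Focal Tversky loss against hand-derived oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermseg.metrics import (ConfusionCounts, TverskyParams, accuracy,
                             confusion_counts, dice, focal_tversky_loss,
                             jaccard, soft_tversky_index, threshold_jaccard,
                             tversky)
from dermseg.nn import Tensor, focal_tversky

from conftest import brute_force_counts, random_mask_pair


class TestConfusionCounts:
    @pytest.mark.parametrize("pred, gt, expected", [
        (np.ones((2, 2)), np.ones((2, 2)), (4, 0, 0, 0)),
        (np.zeros((2, 2)), np.zeros((2, 2)), (0, 0, 4, 0)),
        ([[1, 1], [0, 0]], [[1, 0], [1, 0]], (1, 1, 1, 1)),
    ])
    def test_examples(self, pred, gt, expected):
        c = confusion_counts(np.asarray(pred), np.asarray(gt))
        assert (c.tp, c.fp, c.tn, c.fn) == expected
        assert c.total == np.asarray(pred).size

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(2, 3\)"):
            confusion_counts(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            confusion_counts(np.full((2, 2), 2), np.zeros((2, 2)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestScalarMetrics:
    def test_accuracy(self):
        assert accuracy(ConfusionCounts(1, 1, 1, 1)) == 0.5
        assert accuracy(ConfusionCounts(3, 0, 5, 0)) == 1.0
        assert accuracy(ConfusionCounts(0, 3, 0, 5)) == 0.0
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_dice_and_jaccard(self):
        c = ConfusionCounts(tp=2, fp=1, tn=0, fn=1)
        assert dice(c) == pytest.approx(2 / 3)
        assert jaccard(c) == pytest.approx(0.5)
        perfect = ConfusionCounts(tp=5, fp=0, tn=3, fn=0)
        assert dice(perfect) == jaccard(perfect) == 1.0
        disjoint = ConfusionCounts(tp=0, fp=2, tn=0, fn=3)
        assert dice(disjoint) == jaccard(disjoint) == 0.0

    def test_empty_mask_convention_is_configurable(self):
        empty = ConfusionCounts(tp=0, fp=0, tn=9, fn=0)
        assert dice(empty) == 1.0
        assert dice(empty, empty_value=0.0) == 0.0
        assert jaccard(empty) == 1.0

    @pytest.mark.parametrize("jsi, expected", [
        (0.5, 0.0),          # below the cutoff -> unusable, scored zero
        (0.7, 0.7),
        (0.65, 0.65),        # boundary belongs to the identity branch
        (0.0, 0.0),
        (1.0, 1.0),
    ])
    def test_threshold_jaccard_rule(self, jsi, expected):
        assert threshold_jaccard(jsi) == expected

    def test_threshold_jaccard_domain(self):
        with pytest.raises(ValueError):
            threshold_jaccard(1.2)
        with pytest.raises(ValueError):
            threshold_jaccard(-0.1)

    def test_tversky_examples(self):
        c = ConfusionCounts(tp=2, fp=1, tn=0, fn=1)
        assert tversky(c, 0.5, 0.5) == pytest.approx(2 / 3)
        assert tversky(c, 1.0, 1.0) == pytest.approx(0.5)
        c2 = ConfusionCounts(tp=3, fp=1, tn=0, fn=2)
        assert tversky(c2, 0.7, 0.3) == pytest.approx(3 / 4.7)
        with pytest.raises(ValueError):
            tversky(c, -0.1, 0.5)


class TestMetricProperties:
    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            pred, gt = random_mask_pair(rng)
            tp, fp, tn, fn = brute_force_counts(pred, gt)
            c = confusion_counts(pred, gt)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            ref = ConfusionCounts(tp, fp, tn, fn)
            assert dice(c) == dice(ref)
            assert jaccard(c) == jaccard(ref)
            assert accuracy(c) == accuracy(ref)

    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
           tn=st.integers(0, 1000), fn=st.integers(0, 1000))
    @settings(deadline=None, derandomize=True)
    def test_tversky_generalizes_dice_and_jaccard(self, tp, fp, tn, fn):
        c = ConfusionCounts(tp, fp, tn, fn)
        assert tversky(c, 0.5, 0.5) == dice(c)
        assert tversky(c, 1.0, 1.0) == jaccard(c)

    @given(tp=st.integers(0, 1000), fp=st.integers(0, 1000),
           fn=st.integers(0, 1000))
    @settings(deadline=None, derandomize=True)
    def test_dice_jaccard_identity(self, tp, fp, fn):
        c = ConfusionCounts(tp, fp, 0, fn)
        j = jaccard(c)
        assert dice(c) == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_spatial_permutation_invariance(self, rng):
        pred, gt = random_mask_pair(rng, shape=(6, 7))
        perm = rng.permutation(pred.size)
        pp = pred.ravel()[perm].reshape(pred.shape)
        gp = gt.ravel()[perm].reshape(gt.shape)
        assert confusion_counts(pp, gp) == confusion_counts(pred, gt)


class TestFocalTverskyLoss:
    def test_zero_at_perfect_agreement(self, rng):
        gt = (rng.random((6, 8)) < 0.4).astype(np.uint8)
        loss = focal_tversky_loss(gt.astype(np.float64), gt)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_focal_arithmetic(self):
        # uniform foreground probability on an all-lesion mask gives soft
        # TI = p / (p + alpha (1 - p)), so the focal value is closed-form
        gt = np.ones((10, 10), dtype=np.uint8)
        p1 = TverskyParams(alpha=1.0, beta=1.0, gamma=1.0)
        loss = focal_tversky_loss(np.full((10, 10), 0.6), gt, p1)
        assert loss == pytest.approx(0.4, abs=1e-5)
        p2 = TverskyParams(alpha=1.0, beta=1.0, gamma=2.0)
        loss = focal_tversky_loss(np.full((10, 10), 0.75), gt, p2)
        assert loss == pytest.approx(0.0625, abs=1e-5)

    def test_rejects_out_of_range_probabilities(self):
        gt = np.ones((2, 2), dtype=np.uint8)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            focal_tversky_loss(np.full((2, 2), 1.5), gt)

    def test_monotone_decreasing_in_ti(self):
        for gamma in (0.5, 1.0, 4 / 3, 2.0):
            tis = np.linspace(0, 1, 21)
            losses = (1 - tis) ** gamma
            assert np.all(np.diff(losses) < 1e-12)

    def test_numpy_and_autodiff_paths_agree(self, rng):
        probs_fg = rng.random((3, 6, 8)).astype(np.float32)
        gt = (rng.random((3, 6, 8)) < 0.4).astype(np.float32)
        params = TverskyParams()
        np_loss = focal_tversky_loss(probs_fg, gt, params)
        probs2 = np.stack([1 - probs_fg, probs_fg], axis=1)
        t_loss = focal_tversky(Tensor(probs2), gt, params).item()
        assert t_loss == pytest.approx(np_loss, rel=1e-4)

    def test_gradient_negative_on_true_foreground_pixel(self, rng):
        gt = (rng.random((4, 5)) < 0.5).astype(np.float32)
        gt[1, 2] = 1.0
        probs_fg = rng.uniform(0.2, 0.8, size=(4, 5)).astype(np.float32)
        probs = Tensor(np.stack([1 - probs_fg, probs_fg])[None], requires_grad=True)
        loss = focal_tversky(probs, gt[None], TverskyParams())
        loss.backward()
        # raising the foreground probability of a lesion pixel lowers the loss
        assert probs.grad[0, 1, 1, 2] < 0

    def test_batch_loss_is_mean_of_per_image_losses(self, rng):
        probs = rng.random((4, 6, 8))
        gt = (rng.random((4, 6, 8)) < 0.4).astype(np.uint8)
        batch = focal_tversky_loss(probs, gt)
        singles = [focal_tversky_loss(probs[i], gt[i]) for i in range(4)]
        assert batch == pytest.approx(np.mean(singles), rel=1e-12)

    def test_soft_index_matches_hard_counts_on_binary_input(self, rng):
        pred, gt = random_mask_pair(rng, shape=(16, 16))
        params = TverskyParams(alpha=0.7, beta=0.3)
        soft = soft_tversky_index(pred.astype(float), gt, params)[0]
        hard = tversky(confusion_counts(pred, gt), 0.7, 0.3)
        assert soft == pytest.approx(hard, abs=1e-5)


def test_tversky_params_validation():
    with pytest.raises(ValueError):
        TverskyParams(alpha=-0.1)
    with pytest.raises(ValueError):
        TverskyParams(gamma=0.0)
    with pytest.raises(ValueError):
        TverskyParams(epsilon=0.0)
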