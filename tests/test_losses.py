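"""Cross-entropy and multi-label focal loss: values, limits, gradients."""

import numpy as np
import pytest

from ocsrkit.losses import ce, label_probability, mfl
from ocsrkit.nn.autodiff import Parameter

RNG = np.random.default_rng(7)


class TestLabelProbability:
    def test_zero_logit_both_labels(self):
        assert label_probability(0.0, 1) == pytest.approx(0.5)
        assert label_probability(0.0, 0) == pytest.approx(0.5)

    def test_saturation(self):
        assert label_probability(20.0, 1) == pytest.approx(1.0, abs=1e-8)
        assert label_probability(20.0, 0) == pytest.approx(0.0, abs=1e-8)

    def test_elementwise(self):
        p = label_probability(np.array([0.0, 20.0]), np.array([1, 0]))
        assert p == pytest.approx([0.5, 0.0], abs=1e-8)


class TestMFL:
    def test_hand_computed_two_class_value(self):
        # n=2, logits 0, y=(1,0), gamma=0, alpha=1:
        # (1/2) * (-log 0.5 - log 0.5) = log 2
        logits = np.zeros((1, 2))
        y = np.array([[1.0, 0.0]])
        loss = mfl(logits, y, alpha=1.0, gamma=0.0)
        assert loss.item() == pytest.approx(np.log(2.0), abs=1e-10)

    def test_perfect_prediction_vanishes(self):
        logits = np.array([[40.0, -40.0, -40.0]])
        y = np.array([[1.0, 0.0, 0.0]])
        assert mfl(logits, y, alpha=1.0, gamma=2.0).item() == pytest.approx(0.0, abs=1e-12)

    def test_focusing_factor_bounds_loss(self):
        logits = RNG.standard_normal((5, 8))
        ids = RNG.integers(0, 8, size=5)
        for gamma in (0.5, 1.0, 2.0):
            assert (mfl(logits, ids, alpha=1.0, gamma=gamma).item()
                    <= mfl(logits, ids, alpha=1.0, gamma=0.0).item())

    def test_gamma_zero_equals_mean_binary_cross_entropy(self):
        """MFL(gamma=0, alpha=1) is exactly the mean per-class BCE."""
        logits = RNG.standard_normal((4, 6, 10))
        ids = RNG.integers(0, 10, size=(4, 6))
        onehot = np.eye(10)[ids]
        p = 1.0 / (1.0 + np.exp(-logits))
        bce = -(onehot * np.log(p) + (1 - onehot) * np.log1p(-p)).mean()
        assert mfl(logits, ids, alpha=1.0, gamma=0.0).item() == pytest.approx(
            bce, abs=1e-10)

    def test_monotone_decreasing_in_true_probability(self):
        losses = []
        for true_logit in (-2.0, 0.0, 2.0, 5.0):
            logits = np.array([[true_logit, 0.3, -0.7]])
            losses.append(mfl(logits, np.array([0]), alpha=1.0, gamma=2.0).item())
        assert losses == sorted(losses, reverse=True)

    def test_mask_excludes_pad_positions(self):
        logits = RNG.standard_normal((1, 3, 5))
        ids = np.array([[1, 2, 3]])
        mask = np.array([[1.0, 1.0, 0.0]])
        full = mfl(logits[:, :2], ids[:, :2], alpha=1.0, gamma=2.0)
        masked = mfl(logits, ids, alpha=1.0, gamma=2.0, mask=mask)
        assert masked.item() == pytest.approx(full.item(), rel=1e-12)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            mfl(np.zeros((1, 3)), np.array([0]), alpha=-0.1)
        with pytest.raises(ValueError):
            mfl(np.zeros((1, 3)), np.array([0]), gamma=-1.0)


class TestCE:
    def test_uniform_logits_give_log_n(self):
        for n in (5, 79):
            loss = ce(np.zeros((2, 3, n)), np.zeros((2, 3), np.int64))
            assert loss.item() == pytest.approx(np.log(n), abs=1e-10)

    def test_log_79_value(self):
        assert ce(np.zeros((1, 79)), np.array([4])).item() == pytest.approx(
            4.3694478524670215, abs=1e-9)

    def test_saturated_correct_logit_vanishes(self):
        logits = np.full((1, 4), -30.0)
        logits[0, 2] = 30.0
        assert ce(logits, np.array([2])).item() == pytest.approx(0.0, abs=1e-12)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            ce(np.zeros((1, 2, 3)), np.zeros((1, 2), np.int64),
               mask=np.zeros((1, 2)))


class TestGradients:
    @pytest.mark.parametrize("loss_fn", [
        lambda t, ids: ce(t, ids),
        lambda t, ids: mfl(t, ids, alpha=0.25, gamma=2.0),
        lambda t, ids: mfl(t, ids, alpha=np.linspace(0.1, 1.0, 6), gamma=1.5),
    ])
    def test_numerical_matches_analytic(self, loss_fn):
        x = RNG.standard_normal((3, 6))
        ids = RNG.integers(0, 6, size=3)
        p = Parameter(x)
        p.data = x.copy()
        loss_fn(p, ids).backward()
        analytic = p.grad

        eps = 1e-6
        numeric = np.zeros_like(x)
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                for sign in (1, -1):
                    q = Parameter(x)
                    q.data = x.copy()
                    q.data[i, j] += sign * eps
                    val = loss_fn(q, ids).item()
                    numeric[i, j] += sign * val / (2 * eps)
        rel = np.abs(analytic - numeric).max() / np.abs(numeric).max()
        assert rel < 1e-4
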