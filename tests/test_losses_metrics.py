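"""Joint loss arithmetic and the five derived percentage metrics."""

import numpy as np
import pytest

from seizurecae.losses import (LossWeights, classification_loss,
                               classification_loss_grad, reconstruction_loss,
                               reconstruction_loss_grad, total_loss)
from seizurecae.metrics import (ConfusionCounts, compute_metrics,
                                threshold_predictions)

rng = np.random.default_rng(99)


def bce_oracle(preds, labels, clamp=1e-7):
    total = 0.0
    for p, x in zip(preds, labels):
        p = min(max(p, clamp), 1 - clamp)
        total += x * np.log(p) + (1 - x) * np.log(1 - p)
    return -total / len(preds)


def mse_oracle(orig, recon):
    total = 0.0
    for a, b in zip(orig, recon):
        q = a.reshape(-1)
        r = b.reshape(-1)
        total += sum((u - v) ** 2 for u, v in zip(q, r)) / len(q)
    return total / len(orig)


class TestClassificationLoss:
    def test_uniform_predictions_give_ln2(self):
        preds = np.full(64, 0.5)
        labels = rng.integers(0, 2, 64)
        assert classification_loss(preds, labels) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_perfect_predictions_near_zero(self):
        labels = np.array([0, 1, 1, 0])
        assert classification_loss(labels.astype(float), labels) < 1e-5

    def test_matches_per_element_oracle(self):
        for _ in range(20):
            n = rng.integers(1, 40)
            preds = rng.uniform(0.001, 0.999, n)
            labels = rng.integers(0, 2, n)
            assert classification_loss(preds, labels) == pytest.approx(
                bce_oracle(preds, labels), abs=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([]), np.array([]))

    def test_gradient_matches_finite_difference(self):
        preds = rng.uniform(0.1, 0.9, 10)
        labels = rng.integers(0, 2, 10).astype(float)
        g = classification_loss_grad(preds, labels)
        eps = 1e-7
        for k in range(10):
            up, down = preds.copy(), preds.copy()
            up[k] += eps
            down[k] -= eps
            num = (classification_loss(up, labels)
                   - classification_loss(down, labels)) / (2 * eps)
            assert g[k] == pytest.approx(num, abs=1e-6)


class TestReconstructionLoss:
    def test_identical_inputs_zero(self):
        x = rng.random((3, 8, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_unit_offset_gives_one(self):
        x = rng.random((5, 16, 3))
        assert reconstruction_loss(x, x + 1.0) == pytest.approx(1.0,
                                                                abs=1e-12)

    def test_matches_double_sum_oracle(self):
        x = rng.random((4, 6, 3))
        xhat = rng.random((4, 6, 3))
        assert reconstruction_loss(x, xhat) == pytest.approx(
            mse_oracle(x, xhat), abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_gradient_direction_and_scale(self):
        x = np.zeros((2, 4))
        xhat = np.ones((2, 4))
        g = reconstruction_loss_grad(x, xhat)
        np.testing.assert_allclose(g, 2.0 / (2 * 4))


class TestTotalLoss:
    def test_default_weights_hand_case(self):
        assert total_loss(0.2, 0.1) == pytest.approx(0.2)

    def test_zero_reconstruction_weight_is_pure_classifier(self):
        w = LossWeights(weight_cl=0.5, weight_rlc=0.0)
        assert total_loss(0.8, 123.0, w) == pytest.approx(0.4)

    def test_linearity_in_each_argument(self):
        w = LossWeights()
        for a in (0.0, 0.5, 2.0):
            assert total_loss(a, 0.0, w) == pytest.approx(w.weight_cl * a)
            assert total_loss(0.0, a, w) == pytest.approx(w.weight_rlc * a)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            LossWeights(weight_cl=1.5)
        with pytest.raises(ValueError):
            LossWeights(weight_cl=0.0, weight_rlc=0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(float("nan"), 0.0)


class TestMetrics:
    def test_hand_worked_confusion_case(self):
        m = compute_metrics(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert m.acc == pytest.approx(80.0)
        assert m.se == pytest.approx(75.0)
        assert m.sp == pytest.approx(83.33, abs=0.01)
        assert m.pr == pytest.approx(75.0)
        assert m.f1 == pytest.approx(75.0)

    def test_all_correct_is_all_hundred(self):
        m = compute_metrics(ConfusionCounts(tp=7, tn=9, fp=0, fn=0))
        assert (m.acc, m.se, m.sp, m.pr, m.f1) == (100.0,) * 5

    def test_no_true_positives_zero_sensitivity(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert m.se == 0.0

    def test_zero_denominator_warns_and_reports_zero(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert m.pr == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_agrees_with_sklearn_on_random_batches(self):
        from sklearn.metrics import (accuracy_score, f1_score,
                                     precision_score, recall_score)
        for _ in range(200):
            n = rng.integers(4, 60)
            truth = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            if len(np.unique(truth)) < 2 or len(np.unique(pred)) < 2:
                continue
            counts = ConfusionCounts(
                tp=int(np.sum(pred & truth)),
                tn=int(np.sum(~pred.astype(bool) & ~truth.astype(bool))),
                fp=int(np.sum(pred & ~truth.astype(bool))),
                fn=int(np.sum(~pred.astype(bool) & truth.astype(bool))))
            m = compute_metrics(counts)
            assert m.acc == pytest.approx(
                100 * accuracy_score(truth, pred), abs=1e-9)
            assert m.se == pytest.approx(
                100 * recall_score(truth, pred), abs=1e-9)
            assert m.pr == pytest.approx(
                100 * precision_score(truth, pred), abs=1e-9)
            assert m.f1 == pytest.approx(
                100 * f1_score(truth, pred), abs=1e-9)

    def test_metrics_permutation_invariant(self):
        probs = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        _, c1 = threshold_predictions(probs, labels)
        _, c2 = threshold_predictions(probs[perm], labels[perm])
        assert c1 == c2


class TestThreshold:
    def test_exact_half_goes_to_class_one(self):
        preds, counts = threshold_predictions(np.array([0.5]),
                                              np.array([1]))
        assert preds[0] == 1 and counts.tp == 1

    def test_zero_threshold_everything_positive(self):
        probs = rng.uniform(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        preds, counts = threshold_predictions(probs, labels, tau=0.0)
        assert preds.all()
        assert counts.tn == 0

    def test_counts_sum_to_batch_size(self):
        for _ in range(20):
            n = rng.integers(1, 50)
            _, counts = threshold_predictions(rng.uniform(0, 1, n),
                                              rng.integers(0, 2, n))
            assert counts.total == n
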