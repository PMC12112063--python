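"""Closed forms and oracles for the hybrid objective and evaluation metrics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwseg.losses import LossConfig, dice_loss, focal_loss, hybrid_loss, one_hot
from uwseg.metrics import ConfusionMatrix, miou_mpa, per_class_report, update_confusion
from uwseg.nn import Tensor


def probs_for(pt, num_classes=2):
    """Two-class probability map with constant true-class probability pt."""
    p = np.zeros((1, num_classes, 1, 1), np.float32)
    p[0, 1] = pt
    p[0, 0] = 1 - pt
    return p, np.ones((1, 1, 1), np.int64)


class TestFocal:
    def test_half_confidence_gamma_two(self):
        p, t = probs_for(0.5)
        assert focal_loss(Tensor(p), t, 2.0).item() == pytest.approx(
            0.25 * np.log(2), rel=1e-5)

    def test_perfect_confidence_is_zero(self):
        p, t = probs_for(1.0)
        assert focal_loss(Tensor(p), t, 2.0).item() == pytest.approx(0.0, abs=1e-7)

    def test_gamma_zero_is_cross_entropy(self, rng):
        pt = rng.uniform(0.1, 0.9)
        p, t = probs_for(pt)
        assert focal_loss(Tensor(p), t, 0.0).item() == pytest.approx(
            -np.log(pt), rel=1e-4)

    def test_nonnegative_and_decreasing_in_pt(self):
        vals = [focal_loss(Tensor(probs_for(pt)[0]), probs_for(pt)[1], 2.0).item()
                for pt in (0.2, 0.4, 0.6, 0.8, 0.99)]
        assert all(v >= 0 for v in vals)
        assert vals == sorted(vals, reverse=True)

    def test_zero_probability_is_clamped_not_fatal(self):
        p, t = probs_for(0.0)
        v = focal_loss(Tensor(p), t, 2.0).item()
        assert np.isfinite(v)


class TestDice:
    def test_perfect_overlap_is_zero(self):
        y = np.array([[0, 1], [1, 0]])[None]
        p = Tensor(one_hot(y, 2))
        assert dice_loss(p, y).item() == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_supports_is_one(self):
        truth = np.array([[1, 1], [0, 0]])[None]
        pred = one_hot(np.array([[0, 0], [1, 1]])[None], 2)
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(1.0, abs=1e-4)

    def test_hand_example_one_third(self):
        # y = [1,1,0,0], yhat = [1,0,0,0] -> 1 - 2/(2+1) = 1/3
        truth = np.array([1, 1, 0, 0]).reshape(1, 2, 2)
        pred = one_hot(np.array([1, 0, 0, 0]).reshape(1, 2, 2), 2)
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(1 / 3, rel=1e-4)

    def test_absent_class_skipped(self):
        truth = np.zeros((1, 2, 2), np.int64)       # only background
        pred = one_hot(truth, 5)
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(0.0, abs=1e-6)

    def test_bounded_unit_interval(self, rng):
        for _ in range(10):
            truth = rng.integers(0, 3, (2, 4, 4))
            pred = Tensor(np.moveaxis(
                rng.dirichlet(np.ones(3), (2, 4, 4)).astype(np.float32), -1, 1))
            v = dice_loss(pred, truth).item()
            assert -1e-6 <= v <= 1.0 + 1e-6


class TestHybrid:
    def test_perfect_prediction_is_zero(self):
        y = np.array([[0, 1], [2, 1]])[None]
        p = Tensor(one_hot(y, 3))
        assert hybrid_loss(p, y, LossConfig(class_count=3)).item() == pytest.approx(
            0.0, abs=1e-5)

    def test_dice_weight_zero_reduces_to_focal(self, rng):
        truth = rng.integers(0, 3, (1, 3, 3))
        pred = Tensor(np.moveaxis(
            rng.dirichlet(np.ones(3), (1, 3, 3)).astype(np.float32), -1, 1))
        cfg = LossConfig(dice_weight=0.0, class_count=3)
        assert hybrid_loss(pred, truth, cfg).item() == pytest.approx(
            focal_loss(pred, truth, cfg.gamma).item(), rel=1e-6)

    def test_finite_value_and_gradient_on_random_input(self, rng):
        truth = rng.integers(0, 4, (2, 6, 6))
        logits = Tensor(rng.normal(0, 2, (2, 4, 6, 6)), requires_grad=True)
        from uwseg.losses import segmentation_loss
        loss = segmentation_loss(logits, truth, LossConfig(class_count=4))
        assert np.isfinite(loss.item()) and loss.item() > 0
        loss.backward()
        assert np.isfinite(logits.grad).all()

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(focal_weight=0.0, dice_weight=0.0)


class TestConfusionMatrix:
    def test_diagonal_increment(self):
        cm = ConfusionMatrix(3)
        cm.update(np.full(7, 2), np.full(7, 2))
        assert cm.counts[2, 2] == 7 and cm.total == 7

    def test_accumulation_additivity(self, rng):
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        whole = ConfusionMatrix(3).update(a, b)
        halves = ConfusionMatrix(3).update(a[:20], b[:20]).update(a[20:], b[20:])
        np.testing.assert_array_equal(whole.counts, halves.counts)

    def test_matches_loop_oracle(self, rng):
        pred = rng.integers(0, 2, (5, 5))
        truth = rng.integers(0, 2, (5, 5))
        cm = update_confusion(ConfusionMatrix(2), pred, truth)
        ref = np.zeros((2, 2), np.int64)
        for i in range(5):
            for j in range(5):
                ref[truth[i, j], pred[i, j]] += 1
        np.testing.assert_array_equal(cm.counts, ref)

    def test_ignore_label_excluded(self):
        cm = ConfusionMatrix(2)
        truth = np.array([0, 1, 255, 255])
        pred = np.array([0, 0, 1, 0])
        cm.update(pred, truth)
        assert cm.total == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="labels outside"):
            ConfusionMatrix(2).update(np.array([3]), np.array([0]))

    def test_text_roundtrip(self, tmp_path, rng):
        cm = ConfusionMatrix(3).update(rng.integers(0, 3, 50), rng.integers(0, 3, 50))
        cm.save(tmp_path / "cm.txt")
        np.testing.assert_array_equal(ConfusionMatrix.load(tmp_path / "cm.txt").counts,
                                      cm.counts)


class TestMioUMPA:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(4)
        np.fill_diagonal(cm.counts, 10)
        assert miou_mpa(cm) == (pytest.approx(100.0), pytest.approx(100.0))

    def test_hand_example(self):
        cm = ConfusionMatrix(2)
        cm.counts[...] = [[2, 1], [1, 2]]
        miou, mpa = miou_mpa(cm)
        assert miou == pytest.approx(50.0, abs=1e-9)
        assert mpa == pytest.approx(200 / 3, abs=1e-9)

    def test_class_permutation_invariance(self, rng):
        cm = ConfusionMatrix(4)
        cm.counts[...] = rng.integers(0, 50, (4, 4))
        perm = rng.permutation(4)
        cm2 = ConfusionMatrix(4)
        cm2.counts[...] = cm.counts[np.ix_(perm, perm)]
        assert miou_mpa(cm) == pytest.approx(miou_mpa(cm2), abs=1e-9)

    def test_absent_class_excluded_from_mean(self):
        cm = ConfusionMatrix(3)
        cm.counts[0, 0] = 5
        cm.counts[1, 1] = 5
        miou, mpa = miou_mpa(cm)
        assert miou == pytest.approx(100.0) and mpa == pytest.approx(100.0)

    def test_matches_loop_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            cm = ConfusionMatrix(k)
            cm.counts[...] = rng.integers(0, 30, (k, k))
            if cm.total == 0:
                continue
            ious, pas = [], []
            for i in range(k):
                row = cm.counts[i].sum()
                col = cm.counts[:, i].sum()
                if row + col == 0:
                    continue
                tp = cm.counts[i, i]
                ious.append(tp / (row + col - tp))
                pas.append(tp / row if row else 0.0)
            miou, mpa = miou_mpa(cm)
            assert miou == pytest.approx(100 * np.mean(ious), abs=1e-10)
            assert mpa == pytest.approx(100 * np.mean(pas), abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_iou_never_exceeds_pa(self, seed):
        rng = np.random.default_rng(seed)
        cm = ConfusionMatrix(3)
        cm.counts[...] = rng.integers(0, 40, (3, 3))
        iou, pa, present = cm.per_class()
        for i in range(3):
            if present[i] and cm.counts[i].sum() > 0:
                assert iou[i] <= pa[i] + 1e-12

    def test_report_format(self):
        cm = ConfusionMatrix(2)
        cm.counts[...] = [[8, 2], [1, 9]]
        text = per_class_report(cm, ["background", "echinus"])
        assert text.startswith("class,iou_percent,pa_percent")
        assert "echinus" in text and "mean," in text
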