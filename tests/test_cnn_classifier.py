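import numpy as np
import pytest

from ftirchemo import cnn_classifier as cnn
from ftirchemo.sampling import SplitIndices


def _quadrant_images(rng, n_per_class=8, n_classes=4, size=32):
    """Images whose class is a bright square in one quadrant: separable."""
    imgs, labels = [], []
    half = size // 2
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = 0.1 * rng.random((size, size, 3))
            r0 = (c // 2) * half
            c0 = (c % 2) * half
            img[r0 : r0 + half, c0 : c0 + half] += 0.8
            imgs.append(img)
            labels.append(f"q{c}")
    return np.stack(imgs).astype(np.float32), np.array(labels)


def _split(n, train_frac=0.7):
    idx = np.arange(n)
    cut = int(train_frac * n)
    return SplitIndices(
        {"train": idx[:cut], "test": idx[cut:]},
        {"train": train_frac, "test": 1 - train_frac},
    )


class TestBuild:
    def test_deterministic_initialization(self):
        a = cnn.build_resnet(32, 5, seed=7)
        b = cnn.build_resnet(32, 5, seed=7)
        for (oa, na), (ob, nb) in zip(a.params, b.params):
            assert np.array_equal(getattr(oa, na), getattr(ob, nb))

    def test_output_width_matches_classes(self):
        m = cnn.build_resnet(32, 5, seed=0)
        logits = m.forward(np.zeros((2, 32, 32, 3)))
        assert logits.shape == (2, 5)

    def test_zero_image_finite_logits(self):
        m = cnn.build_resnet(32, 3, seed=0)
        assert np.all(np.isfinite(m.forward(np.zeros((1, 32, 32, 3)))))

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            cnn.build_resnet(32, 1, seed=0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            cnn.build_resnet(16, 3, seed=0)

    def test_parameter_count_positive(self):
        assert cnn.build_resnet(32, 5, seed=0).n_parameters > 0


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = cnn.build_resnet(32, 3, seed=1, channels=4)
        imgs = rng.random((4, 32, 32, 3))
        y = np.array([0, 1, 2, 1])
        m.loss_and_grads(imgs, y)
        for obj, name in [m.params[0], m.params[2], m.params[8], m.params[-2]]:
            W = getattr(obj, name)
            G = getattr(obj, "d" + name).copy()
            idx = tuple(rng.integers(0, s) for s in W.shape)
            eps = 1e-6
            W[idx] += eps
            lp = m.loss_and_grads(imgs, y)
            W[idx] -= 2 * eps
            lm = m.loss_and_grads(imgs, y)
            W[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert G[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestTrain:
    def test_separable_classes_reach_perfect_train_accuracy(self, rng):
        imgs, labels = _quadrant_images(rng)
        sp = _split(len(imgs))
        model = cnn.build_resnet(32, 4, seed=0)
        model, hist = cnn.train(
            model, imgs, labels, sp, epochs=15, seed=0, lr=3e-3, batch_size=4
        )
        assert max(hist.train_accuracy) == 1.0

    def test_shuffled_labels_do_not_generalize(self, rng):
        imgs, labels = _quadrant_images(rng, n_per_class=6)
        shuffled = labels.copy()
        np.random.default_rng(0).shuffle(shuffled)
        sp = _split(len(imgs))
        model = cnn.build_resnet(32, 4, seed=0)
        model, hist = cnn.train(
            model, imgs, shuffled, sp, epochs=15, seed=0, lr=3e-3, batch_size=4
        )
        # memorizes train far better than it predicts held-out shuffled labels
        assert hist.train_accuracy[-1] >= 0.5
        assert hist.test_accuracy[-1] <= 0.5

    def test_zero_epochs_returns_untrained_model(self, rng):
        imgs, labels = _quadrant_images(rng, n_per_class=2)
        sp = _split(len(imgs))
        model = cnn.build_resnet(32, 4, seed=3)
        before = [(o, n, getattr(o, n).copy()) for o, n in model.params]
        model, hist = cnn.train(model, imgs, labels, sp, epochs=0, seed=0)
        assert hist.n_epochs == 0
        for o, n, v in before:
            assert np.array_equal(getattr(o, n), v)

    def test_missing_partition_rejected(self, rng):
        imgs, labels = _quadrant_images(rng, n_per_class=2)
        sp = SplitIndices({"train": np.arange(len(imgs))}, {"train": 1.0})
        model = cnn.build_resnet(32, 4, seed=0)
        with pytest.raises(ValueError, match="test"):
            cnn.train(model, imgs, labels, sp, epochs=1, seed=0)

    def test_seeded_training_reproducible(self, rng):
        imgs, labels = _quadrant_images(rng, n_per_class=3)
        sp = _split(len(imgs))
        hists = []
        for _ in range(2):
            model = cnn.build_resnet(32, 4, seed=9)
            _, hist = cnn.train(
                model, imgs, labels, sp, epochs=3, seed=9, batch_size=4
            )
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].test_accuracy == hists[1].test_accuracy

    def test_history_lengths_equal_epochs(self, rng):
        imgs, labels = _quadrant_images(rng, n_per_class=2)
        sp = _split(len(imgs))
        model = cnn.build_resnet(32, 4, seed=0)
        _, hist = cnn.train(model, imgs, labels, sp, epochs=4, seed=0)
        assert hist.n_epochs == 4
        assert len(hist.train_accuracy) == 4
        assert len(hist.test_loss) == 4


class _StubModel:
    """predict()-only stand-in for evaluate()."""

    def __init__(self, predictions, class_names):
        self._pred = np.asarray(predictions)
        self.class_names = tuple(class_names)

    def predict(self, images):
        return self._pred


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = _StubModel(labels, ["a", "b"])
        counts, acc = cnn.evaluate(model, np.zeros((10, 1, 1, 3)), labels)
        assert acc == 1.0
        for c in ("a", "b"):
            assert counts[c].fp == 0 and counts[c].fn == 0

    def test_all_predicted_one_class(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        model = _StubModel(np.array(["a"] * 10), ["a", "b"])
        counts, acc = cnn.evaluate(model, np.zeros((10, 1, 1, 3)), labels)
        m = cnn.classification_metrics(counts)
        assert m["a"]["SEN"] == 1.0 and m["a"]["SPE"] == 0.0
        assert acc == 0.5

    def test_three_class_hand_tally(self):
        #        true:  a a a b b c
        #        pred:  a b a b c c
        labels = np.array(["a", "a", "a", "b", "b", "c"])
        pred = np.array(["a", "b", "a", "b", "c", "c"])
        model = _StubModel(pred, ["a", "b", "c"])
        counts, acc = cnn.evaluate(model, np.zeros((6, 1, 1, 3)), labels)
        assert acc == pytest.approx(4 / 6)
        assert (counts["a"].tp, counts["a"].fn, counts["a"].fp, counts["a"].tn) == (
            2, 1, 0, 3,
        )
        assert (counts["b"].tp, counts["b"].fn, counts["b"].fp, counts["b"].tn) == (
            1, 1, 1, 3,
        )
        assert (counts["c"].tp, counts["c"].fn, counts["c"].fp, counts["c"].tn) == (
            1, 0, 1, 4,
        )
        for c in counts.values():
            assert c.total == 6


class TestClassificationMetrics:
    def test_sen_arithmetic(self):
        m = cnn.classification_metrics(cnn.ConfusionCounts(9, 0, 0, 1))
        assert m["SEN"] == pytest.approx(0.9)

    def test_spe_and_eff_product(self):
        m = cnn.classification_metrics(cnn.ConfusionCounts(5, 8, 2, 0))
        assert m["SPE"] == pytest.approx(0.8)
        assert m["EFF"] == pytest.approx(m["SEN"] * 0.8)

    def test_perfect_classifier_all_ones(self):
        m = cnn.classification_metrics(cnn.ConfusionCounts(10, 20, 0, 0))
        assert m["SEN"] == m["SPE"] == m["EFF"] == 1.0

    def test_zero_denominator_gives_none(self):
        m = cnn.classification_metrics(cnn.ConfusionCounts(0, 5, 1, 0))
        assert m["SEN"] is None
        assert m["EFF"] is None

    def test_geometric_variant(self):
        m = cnn.classification_metrics(
            cnn.ConfusionCounts(9, 8, 2, 1), eff="geometric"
        )
        assert m["EFF"] == pytest.approx(np.sqrt(0.9 * 0.8))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            cnn.classification_metrics(cnn.ConfusionCounts(1, 1, 1, 1), eff="x")

    def test_eff_bounded_by_sen_and_spe(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 10, 4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = cnn.classification_metrics(
                cnn.ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            )
            assert m["EFF"] <= m["SEN"] + 1e-12
            assert m["EFF"] <= m["SPE"] + 1e-12
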