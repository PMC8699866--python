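"""CNN structure/training, confusion metrics and subject-wise CV integrity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_band_images
from pcglvdd.classify import (
    CNNConfig,
    ConfusionCounts,
    build_cnn,
    confusion_from_predictions,
    confusion_metrics,
    make_cv_plan,
    predict,
    run_cross_validation,
    train_cnn,
)
from pcglvdd.nn import Conv2d, Dense, MaxPool2d, ReLU
from pcglvdd.nn.layers import im2col
from pcglvdd.types import CLASS_INDEX, labels_of


class TestArchitecture:
    def test_layer_shapes_at_128(self):
        from pcglvdd.gan import layer_output_shapes

        params = build_cnn(CNNConfig(image_size=128))
        shapes = layer_output_shapes(params.net, np.zeros((1, 3, 128, 128), np.float32))
        for expected in [(64, 128, 128), (64, 64, 64), (32, 64, 64), (32, 32, 32),
                         (16, 32, 32), (16, 16, 16), (4096,), (128,), (100,), (2,)]:
            assert expected in shapes

    def test_softmax_probabilities_normalized(self, band_images):
        imgs = band_images(2, size=32)
        params = build_cnn(CNNConfig(image_size=32))
        probs, labels = predict(params, imgs)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {0, 1}

    def test_relu_definition_on_grid(self):
        relu = ReLU()
        x = np.linspace(-3, 3, 13).astype(np.float32).reshape(1, -1)
        y = relu.forward(x)
        np.testing.assert_array_equal(y, np.where(x >= 0, x, 0))


class TestTraining:
    def test_separable_classes_reach_high_accuracy(self, band_images):
        train = band_images(50, size=32, seed=1)
        val = band_images(15, size=32, seed=2)
        cfg = CNNConfig(image_size=32, epochs=20, batch_size=32, seed=0)
        params, trace = train_cnn(train, val, cfg, stop_at_val_accuracy=0.95)
        assert trace["val_accuracy"][-1] >= 0.95
        assert len(trace["loss"]) == len(trace["val_accuracy"]) <= cfg.epochs

    def test_loss_decreases_early(self, band_images):
        train = band_images(30, size=32, seed=3)
        cfg = CNNConfig(image_size=32, epochs=6, batch_size=16, seed=1)
        _, trace = train_cnn(train, train[:10], cfg)
        assert trace["loss"][-1] < trace["loss"][0]

    def test_single_class_training_rejected(self, band_images):
        imgs = [im for im in band_images(10, size=32) if im.class_label == "lvdd"]
        with pytest.raises(ValueError):
            train_cnn(imgs, imgs, CNNConfig(image_size=32, epochs=1))

    def test_inference_deterministic(self, band_images):
        imgs = band_images(4, size=32)
        params = build_cnn(CNNConfig(image_size=32))
        p1, _ = predict(params, imgs)
        p2, _ = predict(params, imgs)
        np.testing.assert_array_equal(p1, p2)

    def test_prediction_permutation_equivariant(self, band_images):
        imgs = band_images(4, size=32)
        params = build_cnn(CNNConfig(image_size=32))
        p, _ = predict(params, imgs)
        p_rev, _ = predict(params, imgs[::-1])
        np.testing.assert_allclose(p_rev, p[::-1], rtol=1e-5)


class TestMetrics:
    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(TP=3, FN=1, TN=4, FP=0))
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.75, 1.0, 0.875)

    def test_perfect_counts(self):
        m = confusion_metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_undefined_sensitivity(self):
        with pytest.raises(ZeroDivisionError):
            confusion_metrics(ConfusionCounts(TP=0, FN=0, TN=2, FP=1))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 50), st.integers(0, 50), st.integers(0, 50))
    def test_accuracy_bounded_by_se_sp(self, tp, tn, fp, fn):
        m = confusion_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        assert min(m.sensitivity, m.specificity) - 1e-12 <= m.accuracy
        assert m.accuracy <= max(m.sensitivity, m.specificity) + 1e-12

    def test_confusion_from_predictions(self):
        pos = CLASS_INDEX["lvdd"]
        neg = CLASS_INDEX["control"]
        y = np.array([pos, pos, neg, neg])
        p = np.array([pos, neg, neg, pos])
        c = confusion_from_predictions(y, p)
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)


class TestCVPlan:
    def test_one_subject_per_fold_when_k_equals_n(self, band_images):
        imgs = band_images(10, size=32, n_subjects=5)  # 5 lvdd + 5 control subjects
        plan = make_cv_plan(imgs, k=10, seed=0)
        folds = list(plan.fold_of_subject.values())
        assert sorted(folds) == list(range(10))

    def test_each_fold_tested_exactly_once(self, band_images):
        imgs = band_images(12, size=32, n_subjects=6)
        plan = make_cv_plan(imgs, k=4, seed=0)
        test_folds = [plan.roles(rep)[0] for rep in range(4)]
        assert sorted(test_folds) == list(range(4))

    def test_too_few_subjects(self, band_images):
        imgs = band_images(4, size=32, n_subjects=2)
        with pytest.raises(ValueError):
            make_cv_plan(imgs, k=10)


class _PriorStub:
    """Predict-everything-as-majority stub used to exercise the CV harness."""

    class cfg:
        image_size = 32


class _OracleStub:
    """Stub that reads the band position, i.e. a perfect classifier."""

    def __init__(self, size=32):
        self.size = size


def _oracle_trainer(train_imgs, val_imgs):
    return _OracleStub()


def _oracle_predict(stub, images):
    labels = []
    for im in images:
        top = im.pixels[: im.pixels.shape[0] // 2].sum()
        bottom = im.pixels[im.pixels.shape[0] // 2:].sum()
        labels.append(CLASS_INDEX["lvdd"] if top > bottom else CLASS_INDEX["control"])
    return None, np.array(labels)


class TestCrossValidation:
    def test_perfect_stub_gives_unit_accuracy(self, band_images, monkeypatch):
        import pcglvdd.classify as C

        imgs = band_images(20, size=32, n_subjects=8)
        plan = make_cv_plan(imgs, k=4, seed=0)
        monkeypatch.setattr(C, "predict", _oracle_predict)
        res = C.run_cross_validation(imgs, [], CNNConfig(image_size=32), plan,
                                     trainer=_oracle_trainer, repetitions=4)
        assert res["summary"]["accuracy"]["mean"] == 1.0
        assert res["summary"]["accuracy"]["sd"] == 0.0

    def test_leakage_injection_detected(self, band_images):
        imgs = band_images(20, size=32, n_subjects=8)
        plan = make_cv_plan(imgs, k=4, seed=0)
        # forge an augmented image whose source subject is in the test fold
        test_fold = plan.roles(0)[0]
        victim = next(s for s, f in plan.fold_of_subject.items() if f == test_fold)
        leaked = band_images(1, size=32)[0]
        leaked.origin = "nongenerative_aug"
        leaked.subject_id = victim
        with pytest.raises(ValueError, match="leakage"):
            run_cross_validation(imgs, [leaked], CNNConfig(image_size=32), plan,
                                 trainer=_oracle_trainer, repetitions=1)

    def test_gan_images_join_training_only(self, band_images, monkeypatch):
        import pcglvdd.classify as C

        imgs = band_images(20, size=32, n_subjects=8)
        gan_imgs = band_images(5, size=32)
        for im in gan_imgs:
            im.origin = "gan_generated"
            im.subject_id = ""
        plan = make_cv_plan(imgs, k=4, seed=0)
        seen = {}

        def counting_trainer(train_imgs, val_imgs):
            seen["train"] = train_imgs
            return _OracleStub()

        monkeypatch.setattr(C, "predict", _oracle_predict)
        C.run_cross_validation(imgs, gan_imgs, CNNConfig(image_size=32), plan,
                               trainer=counting_trainer, repetitions=1)
        assert sum(im.origin == "gan_generated" for im in seen["train"]) == len(gan_imgs)
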