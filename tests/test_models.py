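"""Classifier construction, attention contract, two-phase training."""

import numpy as np
import pytest

from drpipe import _autodiff as ad
from drpipe import synth
from drpipe.errors import BackboneUnavailable, EmptyDataset, UnknownBackbone
from drpipe.models import (
    CBAM,
    ClassifierSpec,
    TrainConfig,
    attention_block,
    available_backbones,
    build_classifier,
    load_classifier,
    register_backbone,
    save_classifier,
    train_two_phase,
)


def blob_images(n_per_class=30, n_classes=3, side=32, seed=5):
    """Linearly separable classes rendered as fundus-like images with
    class-specific disc intensity."""
    rng = np.random.default_rng(seed)
    params = synth.FundusParams(side=side, border=3)
    imgs, labels = [], []
    for g in range(n_classes):
        for _ in range(n_per_class):
            imgs.append(synth.make_fundus(params, rng=rng, disc_intensity=60 + 60 * g, lesion_count=0))
            labels.append(g)
    return np.stack(imgs), np.array(labels)


class TestBuildClassifier:
    def test_softmax_rows_sum_to_one(self, rng):
        spec = ClassifierSpec("tiny_test", input_side=32, n_classes=5)
        clf = build_classifier(spec, seed=0)
        x = rng.random((4, 32, 32, 3))
        probs = clf.predict_proba(x)
        assert probs.shape == (4, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_attention_none_drops_the_block(self):
        spec = ClassifierSpec("tiny_test", input_side=32, attention="none")
        clf = build_classifier(spec)
        assert clf.attention is None
        with_attn = build_classifier(ClassifierSpec("tiny_test", input_side=32))
        assert len(with_attn.all_params()) > len(clf.all_params())

    def test_unknown_backbone_raises(self):
        with pytest.raises(UnknownBackbone):
            build_classifier(ClassifierSpec("resnet9000", input_side=32))

    def test_unimplemented_registry_entry_raises(self):
        with pytest.raises(BackboneUnavailable):
            build_classifier(ClassifierSpec("inception_v3", pretrained=True))

    def test_custom_backbone_registration(self):
        from drpipe.models import TinyConvBackbone

        register_backbone("tiny_custom", lambda side, rng: TinyConvBackbone(side, rng))
        assert "tiny_custom" in available_backbones()
        clf = build_classifier(ClassifierSpec("tiny_custom", input_side=16))
        assert clf.predict_proba(np.zeros((1, 16, 16, 3))).shape == (1, 5)


class TestAttentionBlock:
    @pytest.mark.parametrize("shape", [(1, 8, 4, 4), (2, 16, 8, 8), (3, 4, 5, 7)])
    def test_shape_preserved(self, rng, shape):
        feats = rng.normal(size=shape)
        assert attention_block(feats).shape == shape

    def test_gating_never_increases_magnitude(self, rng):
        feats = rng.normal(size=(2, 16, 6, 6))
        out = attention_block(feats)
        assert np.all(np.abs(out) <= np.abs(feats) + 1e-12)

    def test_zero_input_zero_output(self):
        assert np.allclose(attention_block(np.zeros((1, 8, 4, 4))), 0.0)

    def test_constant_feature_map_keeps_shape(self):
        feats = np.full((1, 8, 5, 5), 2.5)
        assert attention_block(feats).shape == feats.shape

    def test_gradients_flow_through_block(self, rng):
        block = CBAM(4, rng=np.random.default_rng(0))
        x = ad.Tensor(rng.normal(size=(2, 4, 4, 4)))
        out = block(x)
        loss = ad.mean(out * out, (0, 1, 2, 3))
        ad.backward(loss)
        assert x.grad is not None and np.any(x.grad != 0)
        assert all(p.grad is not None for p in block.params())


class TestTwoPhaseTraining:
    def test_separable_blobs_reach_high_accuracy(self):
        x, y = blob_images(n_per_class=50)
        spec = ClassifierSpec("tiny_test", input_side=32, n_classes=3)
        clf = build_classifier(spec, seed=0)
        config = TrainConfig(phase1_epochs=15, phase2_epochs=0, batch_size=16, lr_phase1=1e-2, rng_seed=0)
        trained = train_two_phase(clf, (x, y), (x, y), config)
        acc = (clf.predict_proba(x).argmax(axis=1) == y).mean()
        assert acc >= 0.9
        assert 0.0 <= trained.validation_f1 <= 1.0

    def test_zero_epochs_leave_weights_unchanged(self):
        x, y = blob_images(n_per_class=4)
        clf = build_classifier(ClassifierSpec("tiny_test", input_side=32, n_classes=3), seed=1)
        before = [p.data.copy() for p in clf.all_params()]
        train_two_phase(clf, (x, y), (x, y), TrainConfig(phase1_epochs=0, phase2_epochs=0))
        assert all(np.array_equal(a, p.data) for a, p in zip(before, clf.all_params()))

    def test_backbone_frozen_in_phase_one(self):
        x, y = blob_images(n_per_class=6)
        clf = build_classifier(ClassifierSpec("tiny_test", input_side=32, n_classes=3), seed=2)
        backbone_before = [p.data.copy() for p in clf.backbone_params()]
        head_before = [p.data.copy() for p in clf.head_params()]
        train_two_phase(clf, (x, y), (x, y), TrainConfig(phase1_epochs=2, phase2_epochs=0, lr_phase1=1e-2))
        assert all(np.array_equal(a, p.data) for a, p in zip(backbone_before, clf.backbone_params()))
        assert any(not np.array_equal(a, p.data) for a, p in zip(head_before, clf.head_params()))

    def test_phase_two_updates_backbone(self):
        x, y = blob_images(n_per_class=6)
        clf = build_classifier(ClassifierSpec("tiny_test", input_side=32, n_classes=3), seed=3)
        backbone_before = [p.data.copy() for p in clf.backbone_params()]
        train_two_phase(
            clf, (x, y), (x, y), TrainConfig(phase1_epochs=0, phase2_epochs=1, lr_phase2=1e-3)
        )
        assert any(not np.array_equal(a, p.data) for a, p in zip(backbone_before, clf.backbone_params()))

    def test_empty_dataset_raises(self):
        clf = build_classifier(ClassifierSpec("tiny_test", input_side=32, n_classes=3))
        empty = (np.zeros((0, 32, 32, 3)), np.zeros(0, dtype=int))
        x, y = blob_images(n_per_class=2)
        with pytest.raises(EmptyDataset):
            train_two_phase(clf, empty, (x, y), TrainConfig())

    def test_loss_trajectory_reproducible(self):
        x, y = blob_images(n_per_class=5)
        runs = []
        for _ in range(2):
            clf = build_classifier(ClassifierSpec("tiny_test", input_side=32, n_classes=3), seed=4)
            t = train_two_phase(clf, (x, y), (x, y), TrainConfig(phase1_epochs=3, phase2_epochs=0, rng_seed=7))
            runs.append([h["loss"] for h in t.history])
        assert runs[0] == runs[1]


class TestClassWeightedLoss:
    def test_loss_scales_exactly_with_class_weight(self, rng):
        from drpipe.models import _to_input

        clf = build_classifier(ClassifierSpec("tiny_test", input_side=16, n_classes=3), seed=0)
        x = _to_input(rng.random((3, 16, 16, 3)))
        y = np.array([0, 1, 2])
        w = np.array([1.0, 2.0, 4.0])
        base = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x)), y, np.ones(3))
        weighted = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x)), y, w[y])
        # per-sample contributions scale by w; compare per-label slices
        losses = []
        for i in range(3):
            li = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x[i : i + 1])), y[i : i + 1], w[y[i : i + 1]])
            l0 = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x[i : i + 1])), y[i : i + 1], np.ones(1))
            losses.append((float(li.data), float(l0.data)))
        for (lw, lu), wi in zip(losses, w):
            assert lw == pytest.approx(wi * lu)
        assert float(weighted.data) == pytest.approx(sum(l for l, _ in losses) / 3)
        assert float(base.data) == pytest.approx(sum(l for _, l in losses) / 3)

    def test_gradient_scales_with_weights(self, rng):
        from drpipe.models import _to_input

        clf = build_classifier(ClassifierSpec("tiny_test", input_side=16, n_classes=3), seed=1)
        x = _to_input(rng.random((2, 16, 16, 3)))
        y = np.array([1, 1])
        loss1 = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x)), y, np.ones(2))
        ad.backward(loss1)
        g1 = clf.head.w.grad.copy()
        loss2 = ad.softmax_cross_entropy(clf.logits(ad.Tensor(x)), y, np.full(2, 3.0))
        ad.backward(loss2)
        g2 = clf.head.w.grad.copy()
        assert np.allclose(g2, 3.0 * g1)


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, rng):
        clf = build_classifier(ClassifierSpec("tiny_test", input_side=16, n_classes=5), seed=6)
        x = rng.random((3, 16, 16, 3))
        save_classifier(clf, tmp_path / "m")
        back = load_classifier(tmp_path / "m")
        assert back.spec == clf.spec
        assert np.allclose(back.predict_proba(x), clf.predict_proba(x))
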