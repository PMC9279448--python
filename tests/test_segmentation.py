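"""Vessel segmentation: loss arithmetic, network mechanics, backends."""

import math

import numpy as np
import pytest

from retinafd import synthetic as syn
from retinafd.segmentation import (
    SegmentationModelConfig,
    WeightsRequiredError,
    augment,
    bce_loss,
    binarize,
    build_model,
    segment,
    train,
)
from retinafd.segmentation import nn

SMALL = dict(input_side=64, encoder_channels=(8, 16, 32, 64, 128),
             decoder_channels=(128, 64, 32, 16, 8))


class TestBceLoss:
    def test_all_zero_gt_half_pred_is_ln2(self):
        gt = np.zeros((16, 16))
        pred = np.full((16, 16), 0.5)
        assert bce_loss(gt, pred) == pytest.approx(math.log(2), abs=1e-12)

    def test_perfect_prediction_near_zero(self, rng):
        gt = (rng.random((32, 32)) < 0.3).astype(float)
        assert bce_loss(gt, gt) < 1e-6

    def test_single_pixel_closed_form(self):
        assert bce_loss(np.array([[1.0]]), np.array([[math.exp(-1)]])) == \
            pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(10):
            gt = (rng.random((8, 8)) < 0.5).astype(float)
            pred = rng.random((8, 8))
            assert bce_loss(gt, pred) >= 0.0


class TestBinarize:
    def test_all_below_threshold_empty(self):
        assert binarize(np.full((8, 8), 0.4), 0.5).sum() == 0

    def test_tie_goes_to_foreground(self):
        assert binarize(np.full((8, 8), 0.5), 0.5).all()

    def test_counts_match_brute_force(self, rng):
        probs = rng.random((64, 64))
        mask = binarize(probs, 0.37)
        brute = sum(1 for v in probs.ravel() if v >= 0.37)
        assert int(mask.sum()) == brute


class TestModel:
    def test_output_shape_and_range(self, rng):
        model = build_model(SegmentationModelConfig(**SMALL))
        x = rng.random((64, 64, 3))
        p = model.predict(x)
        assert p.shape == (64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_deterministic_forward(self, rng):
        model = build_model(SegmentationModelConfig(**SMALL, seed=5))
        x = rng.random((64, 64, 3))
        np.testing.assert_array_equal(model.predict(x), model.predict(x))

    def test_same_seed_same_weights(self, rng):
        a = build_model(SegmentationModelConfig(**SMALL, seed=7))
        b = build_model(SegmentationModelConfig(**SMALL, seed=7))
        x = rng.random((64, 64, 3))
        np.testing.assert_array_equal(a.predict(x), b.predict(x))

    def test_indivisible_side_rejected(self):
        with pytest.raises(ValueError):
            SegmentationModelConfig(input_side=100,
                                    encoder_channels=(8, 16, 32, 64, 128),
                                    decoder_channels=(128, 64, 32, 16, 8))

    def test_weight_roundtrip(self, tmp_path, rng):
        model = build_model(SegmentationModelConfig(**SMALL, seed=3))
        x = rng.random((64, 64, 3))
        ref = model.predict(x)
        path = tmp_path / "w.npz"
        model.save_weights(path)
        other = build_model(SegmentationModelConfig(**SMALL, seed=99))
        other.load_weights(path)
        np.testing.assert_allclose(other.predict(x), ref, atol=1e-7)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        """Finite differences are the oracle for the analytic backward pass."""
        cfg = SegmentationModelConfig(input_side=8, encoder_channels=(3, 4),
                                      decoder_channels=(4, 3), seed=0)
        model = build_model(cfg)
        x = rng.random((1, 3, 8, 8)).astype(np.float32)
        y = (rng.random((1, 1, 8, 8)) < 0.4).astype(np.float32)

        def loss():
            logits = model.forward_logits(x, train=True)
            return bce_loss(y, nn.sigmoid(logits))

        base = loss()
        p = nn.sigmoid(model.forward_logits(x, train=True))
        model.backward((p - y).astype(np.float32) / y.size)
        checked = 0
        for layer in model.layers():
            for key, param in layer.params.items():
                idx = tuple(rng.integers(0, s) for s in param.shape)
                eps = 1e-3
                orig = param[idx]
                param[idx] = orig + eps
                up = loss()
                param[idx] = orig - eps
                down = loss()
                param[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads[key][idx]
                assert analytic == pytest.approx(numeric, abs=3e-4), \
                    f"{type(layer).__name__}.{key}"
                checked += 1
        assert checked > 10
        assert base > 0


class TestTrain:
    def test_loss_decreases_on_synthetic_pairs(self, small_training_pairs):
        drops = 0
        for seed in range(3):
            cfg = SegmentationModelConfig(**SMALL, epochs=2, seed=seed)
            _, trace = train(build_model(cfg), small_training_pairs, cfg)
            assert len(trace) == 2
            drops += trace[-1] < trace[0]
        assert drops >= 2  # majority of seeds

    def test_overfits_single_pair(self, small_training_pairs):
        cfg = SegmentationModelConfig(**SMALL, epochs=100, learning_rate=5e-3,
                                      seed=0, batch_size=1)
        _, trace = train(build_model(cfg), small_training_pairs[:1], cfg)
        assert trace[-1] < 0.1

    def test_zero_epochs_noop(self, small_training_pairs, rng):
        cfg = SegmentationModelConfig(**SMALL, epochs=0, seed=0)
        model = build_model(cfg)
        x = rng.random((64, 64, 3))
        before = model.predict(x)
        model, trace = train(model, small_training_pairs, cfg)
        assert trace == []
        np.testing.assert_array_equal(model.predict(x), before)

    def test_empty_training_set_rejected(self):
        cfg = SegmentationModelConfig(**SMALL, epochs=1)
        with pytest.raises(ValueError):
            train(build_model(cfg), [], cfg)


class TestAugment:
    def test_reaches_requested_count(self, small_training_pairs):
        out, prov = augment(small_training_pairs[:3], 20, seed=0)
        assert len(out) == 20 and len(prov) == 20

    def test_masks_stay_binary(self, small_training_pairs):
        out, _ = augment(small_training_pairs[:2], 10, seed=1)
        for _, mask in out:
            assert set(np.unique(mask)).issubset({0, 1})

    def test_flip_is_involution(self, small_training_pairs):
        img, _ = small_training_pairs[0]
        np.testing.assert_array_equal(np.flip(np.flip(img, 0), 0), img)

    def test_provenance_reproduces_pairs(self, small_training_pairs):
        from retinafd.segmentation.train import _rotate_pair
        src = small_training_pairs[:2]
        out, prov = augment(src, 8, seed=2)
        for (img, msk), (i, angle, flip) in zip(out[2:], prov[2:]):
            rimg, rmsk = _rotate_pair(np.asarray(src[i][0]), np.asarray(src[i][1]), angle)
            if flip is not None:
                rimg = np.flip(rimg, axis=flip)
                rmsk = np.flip(rmsk, axis=flip)
            np.testing.assert_array_equal(img, rimg)
            np.testing.assert_array_equal(msk, rmsk)

    def test_cannot_shrink(self, small_training_pairs):
        with pytest.raises(ValueError):
            augment(small_training_pairs, 2, seed=0)


class TestSegmentBackends:
    def test_vesselness_recovers_tree(self, default_phantom_512):
        image, gt = default_phantom_512
        mask = binarize(segment(image, backend="vesselness"))
        gt = gt.astype(bool)
        dice = 2 * (mask.astype(bool) & gt).sum() / (mask.sum() + gt.sum())
        assert dice > 0.6

    def test_all_black_image_near_zero(self):
        black = np.zeros((256, 256, 3), dtype=np.uint8)
        probs = segment(black, backend="vesselness", fov_mask=np.ones((256, 256), bool))
        assert probs.max() == 0.0

    def test_cnn_without_weights_errors(self, default_phantom_512):
        with pytest.raises(WeightsRequiredError):
            segment(default_phantom_512[0], backend="cnn")

    def test_unknown_backend(self, default_phantom_512):
        with pytest.raises(ValueError):
            segment(default_phantom_512[0], backend="magic")

    def test_shape_preserved(self, default_phantom_512):
        image, _ = default_phantom_512
        assert segment(image, backend="vesselness").shape == image.pixels.shape[:2]
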