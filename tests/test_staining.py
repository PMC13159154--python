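"""Patch handling, translation-model training/inference, evaluation metrics."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from chipstain.imagecore import Channel, ChipImage
from chipstain.staining import (
    PSNR_CAP_DB,
    PatchSpec,
    TrainConfig,
    TranslationModel,
    evaluate_featurewise,
    evaluate_pixelwise,
    extract_patches,
    predict_fluorescence,
    reassemble_patches,
    train_translation,
)


def img(arr, channel=Channel.BF, bit_depth=16):
    return ChipImage(pixels=np.asarray(arr), channel=channel, bit_depth=bit_depth)


def smooth_field_image(rng, shape=(64, 64), sigma=2.0):
    f = gaussian_filter(rng.uniform(0, 1, size=shape), sigma)
    f = (f - f.min()) / (f.max() - f.min())
    return (f * 65535).astype(np.uint16)


@pytest.fixture(scope="module")
def identity_model():
    """A model trained on the fluorescence = copy-of-BF sanity task."""
    rng = np.random.default_rng(0)
    pairs = [
        (img(p := smooth_field_image(rng)), img(p, Channel.DAPI)) for _ in range(8)
    ]
    hyper = TrainConfig(
        epochs=12, base_filters=8, depth=2, learning_rate=1e-2,
        patch=PatchSpec(16, 4), seed=0,
    )
    model = train_translation(pairs[:6], pairs[6:], Channel.DAPI, hyper)
    return model, pairs


class TestExtractPatches:
    def test_exact_fit_single_patch(self, rng):
        patches = extract_patches(img(rng.uniform(0, 1, (224, 224))), PatchSpec(224, 112))
        assert len(patches) == 1 and patches[0][1] == (0, 0)

    def test_two_patches_no_overlap(self, rng):
        patches = extract_patches(img(rng.uniform(0, 1, (224, 448))), PatchSpec(224, 224))
        assert len(patches) == 2

    def test_count_matches_enumeration_oracle(self, rng):
        h, w, p, s = 300, 1000, 224, 112

        def positions(dim):
            pos = list(range(0, dim - p + 1, s))
            if pos[-1] != dim - p:
                pos.append(dim - p)
            return pos

        patches = extract_patches(img(rng.uniform(0, 1, (h, w))), PatchSpec(p, s))
        assert len(patches) == len(positions(h)) * len(positions(w))

    def test_union_covers_every_pixel(self, rng):
        image = img(rng.uniform(0, 1, (300, 1000)))
        spec = PatchSpec(224, 160)
        cover = np.zeros((300, 1000), dtype=int)
        for patch, (r, c) in extract_patches(image, spec):
            cover[r : r + patch.shape[0], c : c + patch.shape[1]] += 1
        assert (cover > 0).all()

    def test_image_smaller_than_patch(self, rng):
        patches = extract_patches(img(rng.uniform(0, 1, (96, 128))), PatchSpec(224, 112))
        assert len(patches) == 1 and patches[0][0].shape == (96, 128)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PatchSpec(224, 0)
        with pytest.raises(ValueError):
            PatchSpec(224, 300)


class TestReassembly:
    @pytest.mark.parametrize("blend", ["average", "linear_ramp"])
    def test_identity_reassembly_exact(self, rng, blend):
        source = rng.uniform(0, 65535, (100, 260))
        spec = PatchSpec(64, 40, blend=blend)
        patches = extract_patches(img(source), spec)
        out = reassemble_patches(patches, source.shape, spec)
        assert np.allclose(out, source, atol=1e-9)

    def test_blend_of_equal_patches_is_patch_value(self):
        spec = PatchSpec(4, 2)
        patches = [(np.full((4, 4), 7.0), (0, 0)), (np.full((4, 4), 7.0), (0, 2))]
        out = reassemble_patches(patches, (4, 6), spec)
        assert np.allclose(out, 7.0)

    def test_gap_rejected(self):
        spec = PatchSpec(4, 4)
        with pytest.raises(ValueError):
            reassemble_patches([(np.ones((4, 4)), (0, 0))], (4, 12), spec)


class TestTraining:
    def test_identity_task_learns(self, identity_model):
        """Validation MSE on the copy task falls below 1% of target variance."""
        model, pairs = identity_model
        target_var = float(
            np.var(np.stack([p[1].astype_float() / 65535 for p in pairs[6:]]))
        )
        assert model.training_log[-1]["best_val_loss"] < 0.01 * target_var

    def test_identity_prediction_accurate(self, identity_model):
        model, pairs = identity_model
        bf, truth = pairs[7]
        pred = predict_fluorescence(model, bf)
        rmse = np.sqrt(np.mean((pred.pixels - truth.astype_float()) ** 2))
        assert rmse < 0.02 * 65535

    def test_best_val_record_non_increasing(self, identity_model):
        model, _ = identity_model
        best = [row["best_val_loss"] for row in model.training_log]
        assert all(a >= b for a, b in zip(best, best[1:]))

    def test_constant_target_learned(self, rng):
        pairs = [
            (img(smooth_field_image(rng)), img(np.full((64, 64), 30000, np.uint16), Channel.DAPI))
            for _ in range(4)
        ]
        hyper = TrainConfig(epochs=8, base_filters=4, depth=1, learning_rate=1e-2,
                            patch=PatchSpec(16, 8), seed=1)
        model = train_translation(pairs[:3], pairs[3:], Channel.DAPI, hyper)
        assert model.training_log[-1]["best_val_loss"] < 1e-3

    def test_empty_training_set_rejected(self, rng):
        pair = (img(smooth_field_image(rng)), img(smooth_field_image(rng), Channel.DAPI))
        with pytest.raises(ValueError):
            train_translation([], [pair], Channel.DAPI, TrainConfig(epochs=1))

    def test_mismatched_pair_shapes_rejected(self, rng):
        bf = img(rng.uniform(0, 1, (64, 64)))
        fl = img(rng.uniform(0, 1, (64, 96)), Channel.DAPI)
        with pytest.raises(ValueError):
            train_translation([(bf, fl)], [(bf, fl)], Channel.DAPI,
                              TrainConfig(epochs=1, patch=PatchSpec(16, 8)))

    def test_training_deterministic_given_seed(self, rng):
        pairs = [
            (img(p := smooth_field_image(rng)), img(p, Channel.DAPI)) for _ in range(4)
        ]
        hyper = TrainConfig(epochs=2, base_filters=4, depth=1, patch=PatchSpec(16, 8), seed=3)
        m1 = train_translation(pairs[:3], pairs[3:], Channel.DAPI, hyper)
        m2 = train_translation(pairs[:3], pairs[3:], Channel.DAPI, hyper)
        for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
            assert np.array_equal(w1, w2)

    def test_channel_models_independent(self, rng):
        pairs_d = [
            (img(p := smooth_field_image(rng)), img(p, Channel.DAPI)) for _ in range(4)
        ]
        pairs_t = [
            (img(p := smooth_field_image(rng)), img(p, Channel.TRITC)) for _ in range(4)
        ]
        hyper = TrainConfig(epochs=2, base_filters=4, depth=1, patch=PatchSpec(16, 8), seed=3)
        dapi = train_translation(pairs_d[:3], pairs_d[3:], Channel.DAPI, hyper)
        before = dapi.net.get_weights()
        train_translation(pairs_t[:3], pairs_t[3:], Channel.TRITC, hyper)
        for w1, w2 in zip(before, dapi.net.get_weights()):
            assert np.array_equal(w1, w2)


class TestPrediction:
    def test_inference_deterministic(self, identity_model):
        model, pairs = identity_model
        a = predict_fluorescence(model, pairs[6][0])
        b = predict_fluorescence(model, pairs[6][0])
        assert np.array_equal(a.pixels, b.pixels)

    def test_output_matches_input_size_and_range(self, identity_model, rng):
        model, _ = identity_model
        bf = img(rng.uniform(0, 65535, (70, 90)))  # not divisible by 2**depth
        pred = predict_fluorescence(model, bf)
        assert pred.shape == (70, 90)
        assert pred.pixels.min() >= 0 and pred.pixels.max() <= 65535

    def test_flip_ensemble_deterministic_and_accurate(self, identity_model):
        model, pairs = identity_model
        bf, truth = pairs[7]
        a = predict_fluorescence(model, bf, flip_ensemble=True)
        b = predict_fluorescence(model, bf, flip_ensemble=True)
        assert np.array_equal(a.pixels, b.pixels)
        rmse = np.sqrt(np.mean((a.pixels - truth.astype_float()) ** 2))
        assert rmse < 0.02 * 65535

    def test_save_load_round_trip(self, identity_model, tmp_path):
        model, pairs = identity_model
        model.save(tmp_path / "dapi_model")
        loaded = TranslationModel.load(tmp_path / "dapi_model")
        a = predict_fluorescence(model, pairs[6][0])
        b = predict_fluorescence(loaded, pairs[6][0])
        assert np.array_equal(a.pixels, b.pixels)


class TestEvaluatePixelwise:
    def test_identical_images(self, rng):
        a = img(rng.uniform(0, 65535, (64, 64)), Channel.DAPI)
        ssim, psnr = evaluate_pixelwise(a, a)
        assert ssim == pytest.approx(1.0)
        assert psnr == PSNR_CAP_DB

    def test_uniform_offset_closed_form(self, rng):
        truth = rng.uniform(10000, 50000, (64, 64))
        delta = 1000.0
        ssim, psnr = evaluate_pixelwise(
            img(truth + delta, Channel.DAPI), img(truth, Channel.DAPI)
        )
        assert psnr == pytest.approx(10 * np.log10(65535**2 / delta**2), abs=1e-6)

    def test_negative_image_has_negative_ssim(self, rng):
        truth = gaussian_filter(rng.uniform(0, 65535, (64, 64)), 2)
        neg = 65535 - truth
        ssim, _ = evaluate_pixelwise(img(neg, Channel.DAPI), img(truth, Channel.DAPI))
        assert ssim < 0


class TestEvaluateFeaturewise:
    @staticmethod
    def _blob_image(rng, n_blobs):
        base = np.full((48, 48), 500.0)
        yy, xx = np.mgrid[0:48, 0:48]
        for _ in range(n_blobs):
            cx, cy = rng.uniform(6, 42, 2)
            base = np.maximum(base, 45000 * np.exp(-(np.hypot(xx - cx, yy - cy) / 3) ** 4))
        return base

    def test_perfect_prediction_r_is_one(self, rng):
        truths = [img(self._blob_image(rng, n), Channel.DAPI) for n in (1, 3, 5, 8, 12)]
        report = evaluate_featurewise({Channel.DAPI: truths}, {Channel.DAPI: truths})
        assert report.min_pearson == pytest.approx(1.0)
        assert report.mean_ssim["DAPI"] == pytest.approx(1.0)

    def test_intensity_scaling_preserves_correlation(self, rng):
        truths = [img(self._blob_image(rng, n), Channel.DAPI) for n in (1, 3, 5, 8, 12)]
        preds = [img(t.astype_float() * 0.5, Channel.DAPI) for t in truths]
        report = evaluate_featurewise({Channel.DAPI: preds}, {Channel.DAPI: truths})
        assert report.pearson[("DAPI", "sum_intensity")] == pytest.approx(1.0, abs=0.01)

    def test_shuffled_pairing_destroys_correlation(self, rng):
        truths = [img(self._blob_image(rng, n), Channel.DAPI) for n in range(1, 17)]
        shuffled = list(truths)
        np.random.default_rng(0).shuffle(shuffled)
        report = evaluate_featurewise({Channel.DAPI: shuffled}, {Channel.DAPI: truths})
        assert abs(report.pearson[("DAPI", "sum_area")]) < 0.6
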