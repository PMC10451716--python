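"""Crop / alpha-mask / CEAM geometry and the model transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchtest import Roi, apply_alpha_mask, apply_ceam, crop_roi, model_transform
from patchtest.preprocess import AlphaMask, preprocess


def random_image(rng, h=64, w=64):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


class TestCrop:
    def test_exact_subarray(self, rng):
        img = random_image(rng, 480, 480)
        out = crop_roi(img, Roi(0, 0, 110, 110))
        assert out.image.shape == (110, 110, 3)
        assert np.array_equal(out.image, img[:110, :110])

    def test_full_image_is_identity(self, rng):
        img = random_image(rng)
        out = crop_roi(img, Roi(0, 0, 64, 64))
        assert np.array_equal(out.image, img)

    def test_out_of_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            crop_roi(random_image(rng), Roi(32, 32, 80, 80))


class TestAlphaMask:
    def test_constant_image_halved_outside_roi(self):
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        out = apply_alpha_mask(img, Roi(10, 10, 20, 20))
        assert (out.image[10:20, 10:20] == 200).all()
        outside = out.image.copy()
        outside[10:20, 10:20] = 100
        assert (outside == 100).all()

    def test_alpha_one_is_identity(self, rng):
        img = random_image(rng)
        out = apply_alpha_mask(img, Roi(5, 5, 20, 20), background_alpha=1.0)
        assert np.array_equal(out.image, img)

    def test_alpha_zero_is_hard_mask(self, rng):
        img = random_image(rng)
        out = apply_alpha_mask(img, Roi(5, 5, 20, 20), background_alpha=0.0)
        assert (out.image[:5] == 0).all()
        assert np.array_equal(out.image[5:20, 5:20], img[5:20, 5:20])

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_alpha_mask(random_image(rng), Roi(0, 0, 8, 8), background_alpha=1.5)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_elementwise_product_property(self, seed):
        """Masked output equals elementwise I*M within integer rounding; ROI bits identical."""
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(8, 48)), int(rng.integers(8, 48))
        x0, y0 = int(rng.integers(0, w - 4)), int(rng.integers(0, h - 4))
        roi = Roi(x0, y0, x0 + int(rng.integers(2, w - x0)), y0 + int(rng.integers(2, h - y0)))
        img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
        out = apply_alpha_mask(img, roi)
        mask = AlphaMask.for_image((h, w), roi).values
        expected = img.astype(float) * mask[..., None]
        assert np.abs(out.image.astype(float) - expected).max() <= 0.5
        assert np.array_equal(out.image[roi.y0 : roi.y1, roi.x0 : roi.x1], img[roi.y0 : roi.y1, roi.x0 : roi.x1])


class TestCeam:
    def test_composite_height_area1(self, rng):
        img, adj = random_image(rng, 480, 480), random_image(rng, 480, 480)
        out = apply_ceam(img, Roi(10, 10, 120, 120), adj, area_index=1)
        assert out.image.shape == (555, 480, 3)

    def test_strip_is_adjacent_edge_rows(self, rng):
        """The appended strip equals the adjacent area's edge rows (brute-force slices)."""
        img, adj = random_image(rng, 100, 80), random_image(rng, 100, 80)
        out1 = apply_ceam(img, Roi(0, 0, 10, 10), adj, area_index=1, context_rows=25, background_alpha=1.0)
        assert np.array_equal(out1.image[100:], adj[:25])  # top rows of area 2 below area 1
        out2 = apply_ceam(img, Roi(0, 0, 10, 10), adj, area_index=2, context_rows=25, background_alpha=1.0)
        assert np.array_equal(out2.image[:25], adj[-25:])  # bottom rows of area 1 above area 2

    def test_area2_roi_shifted_down(self, rng):
        img, adj = random_image(rng, 100, 80), random_image(rng, 100, 80)
        out = apply_ceam(img, Roi(4, 10, 24, 120 - 100 + 20), adj, area_index=2, context_rows=75)
        assert (out.roi.y0, out.roi.y1) == (85, 115)
        assert (out.roi.x0, out.roi.x1) == (4, 24)

    def test_strip_is_dimmed_with_background(self, rng):
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        adj = np.full((40, 40, 3), 200, dtype=np.uint8)
        out = apply_ceam(img, Roi(10, 10, 20, 20), adj, area_index=1, context_rows=10)
        assert (out.image[40:] == 100).all()

    def test_zero_context_equals_alpha_mask(self, rng):
        img, adj = random_image(rng), random_image(rng)
        ceam = apply_ceam(img, Roi(5, 5, 20, 20), adj, area_index=1, context_rows=0)
        am = apply_alpha_mask(img, Roi(5, 5, 20, 20))
        assert np.array_equal(ceam.image, am.image)

    def test_roi_pixels_preserved(self, rng):
        img, adj = random_image(rng), random_image(rng)
        roi = Roi(5, 8, 25, 30)
        out = apply_ceam(img, roi, adj, area_index=2, context_rows=12)
        assert np.array_equal(out.image[out.roi.y0 : out.roi.y1, out.roi.x0 : out.roi.x1],
                              img[roi.y0 : roi.y1, roi.x0 : roi.x1])

    def test_width_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_ceam(random_image(rng, 64, 64), Roi(0, 0, 8, 8), random_image(rng, 64, 32), area_index=1)

    def test_context_rows_exceeding_adjacent_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_ceam(random_image(rng), Roi(0, 0, 8, 8), random_image(rng), area_index=1, context_rows=64)


class TestModelTransform:
    def test_output_shape_and_dtype(self, rng):
        sample = preprocess("am", random_image(rng), Roi(5, 5, 20, 20))
        out = model_transform(sample)
        assert out.shape == (3, 224, 224) and out.dtype == np.float32

    def test_eval_mode_deterministic(self, rng):
        sample = preprocess("crop", random_image(rng), Roi(5, 5, 30, 30))
        a, b = model_transform(sample), model_transform(sample)
        assert np.array_equal(a, b)

    def test_train_mode_seeded_deterministic(self, rng):
        sample = preprocess("crop", random_image(rng), Roi(5, 5, 30, 30))
        a = model_transform(sample, train_mode=True, rng=np.random.default_rng(99))
        b = model_transform(sample, train_mode=True, rng=np.random.default_rng(99))
        c = model_transform(sample, train_mode=True, rng=np.random.default_rng(100))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_train_mode_requires_rng(self, rng):
        sample = preprocess("crop", random_image(rng), Roi(5, 5, 30, 30))
        with pytest.raises(ValueError):
            model_transform(sample, train_mode=True)

    def test_normalization_matches_imagenet_constants(self):
        from patchtest.preprocess import IMAGENET_MEAN, IMAGENET_STD

        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        out = model_transform(preprocess("am", img, Roi(0, 0, 32, 32), background_alpha=1.0))
        expected = (1.0 - IMAGENET_MEAN) / IMAGENET_STD
        assert np.allclose(out[:, 0, 0], expected, atol=1e-5)
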