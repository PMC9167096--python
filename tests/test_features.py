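"""Shape moments, equivalent-ellipse axes, color/texture features, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nevuscope import (FeatureVector, SyntheticLesionSpec, aspect_ratio,
                       central_moment, centroid, color_distance, compute_moments,
                       ellipse_axes, extract_color_features,
                       extract_shape_features, extract_texture_features,
                       fuse_features, generate_lesion_image, geometric_moment)
from nevuscope.synthgen import ellipse_mask

from oracles import brute_force_central_moment, brute_force_moment


def _mask_from_pixels(pixels, shape=(10, 10)):
    mask = np.zeros(shape, dtype=np.uint8)
    for r, c in pixels:
        mask[r, c] = 1
    return mask


class TestGeometricMoments:
    def test_s00_is_area(self):
        mask = _mask_from_pixels([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4)])
        assert geometric_moment(mask, 0, 0) == 5.0

    def test_first_order_example(self):
        mask = _mask_from_pixels([(1, 1), (2, 2)])
        assert geometric_moment(mask, 1, 0) == 3.0
        assert geometric_moment(mask, 0, 1) == 3.0

    @pytest.mark.parametrize("p,q", [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1)])
    def test_random_masks_match_double_loop(self, rng, p, q):
        for _ in range(5):
            mask = (rng.random((20, 20)) < 0.3).astype(np.uint8)
            if not mask.any():
                continue
            assert geometric_moment(mask, p, q) == pytest.approx(
                brute_force_moment(mask, p, q), abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            geometric_moment(np.zeros((5, 5), dtype=np.uint8), 0, 0)


class TestCentroid:
    def test_solid_square(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        assert centroid(mask) == (2.0, 2.0)

    def test_single_pixel(self):
        assert centroid(_mask_from_pixels([(7, 4)])) == (7.0, 4.0)

    @given(dr=st.integers(0, 10), dc=st.integers(0, 10))
    @settings(deadline=None, max_examples=20)
    def test_translation_equivariance(self, dr, dc):
        base = _mask_from_pixels([(1, 2), (3, 1), (2, 4), (0, 0)], shape=(6, 6))
        shifted = np.zeros((20, 20), dtype=np.uint8)
        shifted[dr:dr + 6, dc:dc + 6] = base
        r0, c0 = centroid(base)
        r1, c1 = centroid(shifted)
        assert (r1, c1) == pytest.approx((r0 + dr, c0 + dc))


class TestCentralMoments:
    def test_first_central_moments_vanish(self, rng):
        for _ in range(10):
            mask = (rng.random((15, 15)) < 0.4).astype(np.uint8)
            if not mask.any():
                continue
            assert central_moment(mask, 1, 0) == pytest.approx(0.0, abs=1e-9)
            assert central_moment(mask, 0, 1) == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_line(self):
        mask = _mask_from_pixels([(3, c) for c in range(5)], shape=(8, 8))
        assert central_moment(mask, 0, 2) == pytest.approx(10.0)
        assert central_moment(mask, 2, 0) == pytest.approx(0.0)

    def test_matches_double_loop(self, rng):
        for _ in range(5):
            mask = (rng.random((18, 18)) < 0.35).astype(np.uint8)
            if not mask.any():
                continue
            for p, q in [(2, 0), (0, 2), (1, 1)]:
                assert central_moment(mask, p, q) == pytest.approx(
                    brute_force_central_moment(mask, p, q), abs=1e-9)

    def test_translation_invariance(self):
        base = _mask_from_pixels([(1, 1), (2, 3), (4, 2)], shape=(6, 6))
        shifted = np.zeros((16, 16), dtype=np.uint8)
        shifted[5:11, 7:13] = base
        for p, q in [(2, 0), (0, 2), (1, 1)]:
            assert central_moment(shifted, p, q) == pytest.approx(
                central_moment(base, p, q), abs=1e-9)


class TestEllipseAxes:
    def test_axis_aligned_ellipse_full_lengths(self):
        mask = ellipse_mask(128, 128, (63.5, 63.5), (20, 10), 0.0)
        L1, L2 = ellipse_axes(compute_moments(mask.astype(np.uint8)))
        assert L1 == pytest.approx(40.0, rel=0.05)
        assert L2 == pytest.approx(20.0, rel=0.05)

    def test_disc_axes_equal(self):
        mask = ellipse_mask(64, 64, (31.5, 31.5), (15, 15), 0.0)
        L1, L2 = ellipse_axes(compute_moments(mask.astype(np.uint8)))
        assert L1 == pytest.approx(L2, rel=0.02)
        assert L1 == pytest.approx(30.0, rel=0.05)

    @pytest.mark.parametrize("rot", [0.3, 0.9, 1.4, 2.2])
    def test_rotation_invariance(self, rot):
        ref = ellipse_axes(compute_moments(
            ellipse_mask(128, 128, (63.5, 63.5), (25, 12), 0.0).astype(np.uint8)))
        rotated = ellipse_axes(compute_moments(
            ellipse_mask(128, 128, (63.5, 63.5), (25, 12), rot).astype(np.uint8)))
        assert rotated[0] == pytest.approx(ref[0], rel=0.02)
        assert rotated[1] == pytest.approx(ref[1], rel=0.02)

    def test_collinear_mask_degenerates_with_warning(self, caplog):
        mask = _mask_from_pixels([(2, c) for c in range(6)], shape=(8, 8))
        with caplog.at_level("WARNING", logger="nevuscope"):
            L1, L2 = ellipse_axes(compute_moments(mask))
        assert L2 == 0.0


class TestAspectRatio:
    @pytest.mark.parametrize("axes,expected", [((10, 10), 1.0), ((40, 20), 2.0)])
    def test_known_values(self, axes, expected):
        assert aspect_ratio(axes) == pytest.approx(expected)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            aspect_ratio((10.0, 0.0))

    @pytest.mark.parametrize("scale", [0.5, 0.75, 1.5, 2.0])
    def test_scale_invariance(self, scale):
        a, b = 20.0, 12.0
        ref_mask = ellipse_mask(160, 160, (79.5, 79.5), (a, b), 0.0).astype(np.uint8)
        sc_mask = ellipse_mask(160, 160, (79.5, 79.5), (a * scale, b * scale), 0.0).astype(np.uint8)
        ar_ref = aspect_ratio(ellipse_axes(compute_moments(ref_mask)))
        ar_sc = aspect_ratio(ellipse_axes(compute_moments(sc_mask)))
        assert ar_sc == pytest.approx(ar_ref, rel=0.03)


class TestColorTextureFeatures:
    def test_uniform_lesion_statistics(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        img[mask.astype(bool)] = (100, 50, 25)
        fv = extract_color_features(img, mask)
        assert fv.values[:3] == pytest.approx([100, 50, 25])
        assert fv.values[3:6] == pytest.approx([0, 0, 0])
        # contrast equals the color distance of the two mean vectors
        assert fv.values[6] == pytest.approx(color_distance((100, 50, 25), (255, 255, 255)))

    def test_masked_statistics_match_brute_force(self, rng):
        img = rng.integers(0, 256, size=(24, 24, 3)).astype(np.uint8)
        mask = np.zeros((24, 24), dtype=np.uint8)
        mask[4:16, 6:20] = 1
        fv = extract_color_features(img, mask)
        inside = img[mask.astype(bool)].astype(float)
        assert fv.values[:3] == pytest.approx(inside.mean(axis=0))
        assert fv.values[3:6] == pytest.approx(inside.std(axis=0))

    def test_full_mask_rejected(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="background"):
            extract_color_features(img, np.ones((16, 16), dtype=np.uint8))

    def test_constant_lesion_texture_zero(self):
        img = np.full((32, 32, 3), 80, dtype=np.uint8)
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        fv = extract_texture_features(img, mask)
        assert fv.values == pytest.approx([0, 0, 0, 0])

    def test_entropy_bounded_by_log2_bins(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        mask = np.ones((32, 32), dtype=np.uint8)
        fv = extract_texture_features(img, mask)
        assert 0 <= fv.values[1] <= 5.0

    def test_groove_texture_raises_gradients(self):
        # oblique grooves so both gradient directions are exercised
        spec = SyntheticLesionSpec(semi_axes=(22, 16), rotation=0.6, seed=3)
        flat = generate_lesion_image(spec)
        grooved = generate_lesion_image(spec, nevus_type="acral")
        mask = flat.truth_mask
        f_flat = extract_texture_features(flat.image, mask)
        f_gro = extract_texture_features(grooved.image, mask)
        assert f_gro.values[2] > f_flat.values[2]
        assert f_gro.values[3] > f_flat.values[3]


class TestFusion:
    def test_lengths_add_and_schema_order(self, clean_lesion):
        shape = extract_shape_features(clean_lesion.truth_mask)
        ct = extract_color_features(clean_lesion.image, clean_lesion.truth_mask)
        fused = fuse_features(shape, ct)
        assert len(fused.values) == len(shape.values) + len(ct.values)
        assert fused.schema == shape.schema + ct.schema
        assert fused.view_tag == "fused"
        assert np.array_equal(fused.values,
                              np.concatenate([shape.values, ct.values]))

    def test_fuse_with_empty_is_identity(self):
        a = FeatureVector(values=np.array([1.0, 2.0]), schema=("x", "y"), view_tag="shape")
        empty = FeatureVector(values=np.array([]), schema=(), view_tag="shape")
        fused = fuse_features(a, empty)
        assert np.array_equal(fused.values, a.values)
        assert fused.schema == a.schema

    def test_duplicate_names_rejected(self):
        a = FeatureVector(values=np.array([1.0]), schema=("x",), view_tag="shape")
        b = FeatureVector(values=np.array([2.0]), schema=("x",), view_tag="shape")
        with pytest.raises(ValueError, match="duplicate"):
            fuse_features(a, b)


def test_feature_extraction_deterministic(clean_lesion):
    a = extract_shape_features(clean_lesion.truth_mask)
    b = extract_shape_features(clean_lesion.truth_mask)
    assert np.array_equal(a.values, b.values)
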