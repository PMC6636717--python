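"""The nine per-nucleus parameters and the decorrelation length-scale."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nucleomorph as nm
from nucleomorph import features as ft
from nucleomorph.core import NucleusImage, NucleusMask

from helpers import (
    brute_force_decorrelation,
    hull_fill_concavity,
    make_disk_mask,
    make_random_circular_crop,
)

PX = 0.2


def _const_image(mask, value=0.5, px=PX):
    out = np.zeros(mask.shape)
    out[mask.pixels] = value
    return NucleusImage(out, px)


class TestMorphometrics:
    def test_projected_area_arithmetic(self):
        mask = NucleusMask(np.ones((50, 50), bool))
        assert ft.projected_area(mask, 0.2) == pytest.approx(2500 * 0.04)
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert ft.projected_area(NucleusMask(single), 0.043) == pytest.approx(
            0.043**2
        )

    def test_disk_aspect_ratio_is_one(self):
        mask = NucleusMask(make_disk_mask(30))
        assert ft.aspect_ratio(mask) == pytest.approx(1.0, abs=0.02)

    def test_generated_ellipse_aspect_ratio(self):
        mask = nm.generate_shape(nm.ShapeSpec(area_um2=150, aspect_ratio=2, seed=4), PX)
        assert 1.9 <= ft.aspect_ratio(mask) <= 2.1

    def test_collinear_mask_degenerate(self):
        line = np.zeros((3, 60), bool)
        line[1, 5:55] = True
        with pytest.raises(ValueError, match="degenerate|collinear"):
            ft.aspect_ratio(NucleusMask(line))

    def test_disk_perimeter_estimator(self):
        mask = NucleusMask(make_disk_mask(50))
        assert ft.perimeter(mask, 1.0) == pytest.approx(2 * math.pi * 50, rel=0.03)

    def test_rectangle_perimeter(self):
        rect = np.zeros((60, 100), bool)
        rect[10:50, 10:90] = True  # 40 x 80
        assert ft.perimeter(NucleusMask(rect), 1.0) == pytest.approx(
            2 * (40 + 80), rel=0.05
        )

    def test_shape_factor_closed_forms(self):
        # exact circle: P = 2 pi r, A = pi r^2 -> exactly 1
        r = 7.3
        assert ft.shape_factor(2 * math.pi * r, math.pi * r**2) == pytest.approx(1.0)
        # square side s: P = 4s, A = s^2 -> 4/pi
        assert ft.shape_factor(4 * 5.0, 25.0) == pytest.approx(4 / math.pi)

    def test_rasterized_square_shape_factor(self):
        sq = np.zeros((70, 70), bool)
        sq[10:60, 10:60] = True
        mask = NucleusMask(sq)
        sf = ft.shape_factor(ft.perimeter(mask, 1.0), ft.projected_area(mask, 1.0))
        assert sf == pytest.approx(4 / math.pi, rel=0.05)

    def test_rasterized_disk_shape_factor_band(self):
        for radius in (20, 35, 50):
            mask = NucleusMask(make_disk_mask(radius))
            sf = ft.shape_factor(ft.perimeter(mask, 1.0), ft.projected_area(mask, 1.0))
            assert 0.95 <= sf <= 1.10

    def test_convex_ellipse_concavity_near_zero(self):
        mask = nm.generate_shape(nm.ShapeSpec(area_um2=150, aspect_ratio=1.8, seed=6), PX)
        assert ft.relative_concavity(mask) <= 0.01

    def test_crescent_matches_hull_fill_oracle(self):
        rr, cc = np.mgrid[0:101, 0:101].astype(float)
        crescent = ((rr - 50) ** 2 + (cc - 50) ** 2 <= 40**2) & ~(
            (rr - 50) ** 2 + (cc - 85) ** 2 <= 25**2
        )
        mask = NucleusMask(crescent)
        assert ft.relative_concavity(mask) == pytest.approx(
            hull_fill_concavity(crescent), abs=0.01
        )

    def test_isoperimetric_minimum_of_disk(self):
        """The disk has the smallest shape factor among same-area shapes."""
        disk = nm.generate_shape(nm.ShapeSpec(area_um2=150, seed=1), PX)
        sf_disk = ft.shape_factor(ft.perimeter(disk, PX), ft.projected_area(disk, PX))
        for spec in [
            nm.ShapeSpec(area_um2=150, aspect_ratio=2, seed=2),
            nm.ShapeSpec(area_um2=150, aspect_ratio=3, seed=3),
            nm.ShapeSpec(area_um2=150, concavity_target=0.2, seed=4),
            nm.ShapeSpec(area_um2=150, aspect_ratio=1.5, concavity_target=0.1, seed=5),
        ]:
            mask = nm.generate_shape(spec, PX)
            sf = ft.shape_factor(ft.perimeter(mask, PX), ft.projected_area(mask, PX))
            assert sf_disk <= sf


class TestCentreCentroidMismatch:
    def test_constant_intensity_is_zero(self, disk_mask):
        img = _const_image(disk_mask)
        assert ft.centre_centroid_mismatch(disk_mask, img, PX) == pytest.approx(0.0)

    def test_half_disk_closed_form(self):
        # disk radius R, intensity 1 on left half, 0.5 on right half:
        # weighted centroid offset = 4R/(9*pi) from the center
        R = 40
        disk = make_disk_mask(R, pad=3)
        n = disk.shape[0]
        c = (n - 1) / 2
        img = np.zeros((n, n))
        cols = np.arange(n)
        img[:, cols <= c] = 1.0
        img[:, cols > c] = 0.5
        img[~disk] = 0
        mismatch = ft.centre_centroid_mismatch(
            NucleusMask(disk), NucleusImage(img, 1.0), 1.0
        )
        assert mismatch == pytest.approx(4 * R / (9 * math.pi), rel=0.05)

    def test_even_symmetric_grating_centroids_agree(self):
        # cosine grating phase-locked to the mask center: the intensity is
        # even about the centroid, so weighted and unweighted centroids match
        n = 69
        sq = np.zeros((n, n), bool)
        sq[2:67, 2:67] = True  # 65 px, center row/col 34
        mask = NucleusMask(sq)
        rr = np.mgrid[0:n, 0:n][0].astype(float)
        img = np.zeros((n, n))
        img[sq] = (0.5 + 0.5 * np.cos(2 * math.pi * (rr[sq] - 34) / 16))
        assert ft.centre_centroid_mismatch(
            mask, NucleusImage(img, PX), PX
        ) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_intensities_error(self, disk_mask):
        img = NucleusImage(np.zeros(disk_mask.shape), PX)
        with pytest.raises(ValueError):
            ft.centre_centroid_mismatch(disk_mask, img, PX)


class TestIntensityStatistics:
    def test_entropy_trivial_cases(self, disk_mask):
        assert ft.intensity_entropy(_const_image(disk_mask), disk_mask) == 0.0
        # two equally frequent values -> 1 bit
        px = np.zeros(disk_mask.shape)
        rr = np.nonzero(disk_mask.pixels)
        half = len(rr[0]) // 2
        px[rr[0][:half], rr[1][:half]] = 1.0
        px[rr[0][half:], rr[1][half:]] = 0.5
        ent = ft.intensity_entropy(NucleusImage(px, PX), disk_mask)
        assert ent == pytest.approx(1.0, abs=0.02)

    def test_entropy_uniform_approaches_8_bits(self, disk_mask):
        rng = np.random.default_rng(11)
        px = np.zeros(disk_mask.shape)
        px[disk_mask.pixels] = rng.random(disk_mask.area_px)
        ent = ft.intensity_entropy(NucleusImage(px, PX), disk_mask)
        # multinomial sampling bias ~ (B-1)/(2 N ln 2) ~ 0.02 bits at N=2500
        assert ent == pytest.approx(8.0, abs=0.15)

    def test_sd_trivial_and_analytic_cases(self, disk_mask):
        assert ft.sd_normalized_intensities(_const_image(disk_mask), disk_mask) == 0.0
        px = np.zeros(disk_mask.shape)
        rr = np.nonzero(disk_mask.pixels)
        half = len(rr[0]) // 2
        px[rr[0][:half], rr[1][:half]] = 1.0
        px[rr[0][half:], rr[1][half:]] = 1e-12  # keep strictly two levels after norm
        sd = ft.sd_normalized_intensities(NucleusImage(px, PX), disk_mask)
        assert sd == pytest.approx(0.5, abs=0.01)

    def test_sd_uniform_matches_analytic(self, disk_mask):
        rng = np.random.default_rng(12)
        px = np.zeros(disk_mask.shape)
        px[disk_mask.pixels] = rng.random(disk_mask.area_px)
        sd = ft.sd_normalized_intensities(NucleusImage(px, PX), disk_mask)
        assert sd == pytest.approx(1 / math.sqrt(12), abs=0.01)


class TestInscribedCircle:
    def test_disk_inscribed_circle_is_the_disk(self):
        mask = NucleusMask(make_disk_mask(30))
        img = nm.generate_texture(mask, nm.TextureSpec(length_scale_um=1.0, seed=1), PX)
        circ = ft.crop_inscribed_circle(img, mask)
        assert circ.radius_px == pytest.approx(30, abs=1)

    def test_ellipse_inscribed_radius_is_minor_semi_axis(self):
        mask = nm.generate_shape(nm.ShapeSpec(area_um2=200, aspect_ratio=2, seed=2), PX)
        # area = pi a b, a = 2b -> b = sqrt(area_px / (2 pi))
        b = math.sqrt((200 / PX**2) / (2 * math.pi))
        img = nm.generate_texture(mask, nm.TextureSpec(length_scale_um=1.0, seed=3), PX)
        circ = ft.crop_inscribed_circle(img, mask)
        assert circ.radius_px == pytest.approx(b, abs=1.5)

    def test_crop_is_zero_mean(self, textured_nucleus):
        img, mask = textured_nucleus
        circ = ft.crop_inscribed_circle(img, mask)
        assert abs(circ.values[circ.support].mean()) < 1e-9

    def test_too_small_mask_raises(self):
        mask = NucleusMask(make_disk_mask(3))
        img = _const_image(mask)
        with pytest.raises(ft.InscribedCircleTooSmall):
            ft.crop_inscribed_circle(img, mask)


class TestDecorrelationCurve:
    def test_zero_shift_coefficient_is_one(self, textured_nucleus):
        img, mask = textured_nucleus
        curve = ft.decorrelation_curve(ft.crop_inscribed_circle(img, mask))
        assert curve.shift_distances[0] == 0
        assert curve.mean_coefficients[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            circ = make_random_circular_crop(32, 15.0, rng)
            curve = ft.decorrelation_curve(circ)
            coeff, dists, means = brute_force_decorrelation(circ)
            for (dr, dc), v in coeff.items():
                got = curve.coefficient_map[curve.center[0] + dr, curve.center[1] + dc]
                assert got == pytest.approx(v, abs=1e-6)
            common = np.isin(curve.shift_distances, dists)
            assert np.allclose(
                curve.mean_coefficients[common], means, atol=1e-6
            )

    def test_grating_along_direction_zero_at_quarter_period(self):
        mask = nm.generate_shape(nm.ShapeSpec(area_um2=250, seed=5), PX)
        img = nm.generate_texture(
            mask, nm.TextureSpec(texture_kind="cosine_grating", grating_period_px=16), PX
        )
        curve = ft.decorrelation_curve(ft.crop_inscribed_circle(img, mask))
        d, c = ft.directional_curve(curve, 0.0)  # grating runs along rows
        zc = ft._first_zero_crossing(d, c)
        assert zc == pytest.approx(4.0, rel=0.1)

    def test_degenerate_crop_rejected(self, disk_mask):
        circ = ft.crop_inscribed_circle(_const_image(disk_mask), disk_mask)
        assert circ.degenerate
        with pytest.raises(ValueError):
            ft.decorrelation_curve(circ)


class TestZeroCrossing:
    def test_linear_interpolation(self):
        curve = ft.DecorrelationCurve(
            shift_distances=np.array([0.0, 1.0, 2.0]),
            mean_coefficients=np.array([1.0, 0.5, -0.5]),
            zero_crossing_px=None,
            coefficient_map=np.zeros((1, 1)),
            center=(0, 0),
            bin_counts=np.array([1, 1, 1]),
            pixel_size_um=1.0,
        )
        assert ft.zero_crossing_length(curve, 1.0) == pytest.approx(1.5)

    def test_never_crossing_returns_missing(self):
        curve = ft.DecorrelationCurve(
            shift_distances=np.arange(4.0),
            mean_coefficients=np.array([1.0, 0.8, 0.5, 0.3]),
            zero_crossing_px=None,
            coefficient_map=np.zeros((1, 1)),
            center=(0, 0),
            bin_counts=np.ones(4, int),
            pixel_size_um=1.0,
        )
        assert ft.zero_crossing_length(curve, 1.0) is None

    def test_grating_length_scale_in_um(self):
        mask = nm.generate_shape(nm.ShapeSpec(area_um2=250, seed=5), PX)
        img = nm.generate_texture(
            mask,
            nm.TextureSpec(
                texture_kind="cosine_grating",
                grating_period_px=16,
                grating_orientation=0.9,
            ),
            PX,
        )
        curve = ft.decorrelation_curve(ft.crop_inscribed_circle(img, mask))
        d, c = ft.directional_curve(curve, 0.9)
        zc_um = ft._first_zero_crossing(d, c) * PX
        assert zc_um == pytest.approx(0.8, rel=0.1)


class TestExtractFeatures:
    def test_constant_disk_composition(self, disk_mask):
        fv = ft.extract_features(_const_image(disk_mask), disk_mask)
        assert fv.projected_area_um2 == pytest.approx(100, rel=0.02)
        assert fv.entropy_bits == 0.0
        assert fv.sd_normalized_intensities == 0.0
        assert fv.centre_centroid_mismatch_um == pytest.approx(0.0)
        assert fv.autocorrelation_length_scale_um is None

    def test_generated_nucleus_matches_ground_truth(self):
        spec = nm.ShapeSpec(area_um2=150, aspect_ratio=1.5, concavity_target=0.15, seed=7)
        mask = nm.generate_shape(spec, PX)
        img = nm.generate_texture(mask, nm.TextureSpec(length_scale_um=0.8, seed=8), PX)
        fv = ft.extract_features(img, mask)
        assert fv.projected_area_um2 == pytest.approx(150, rel=0.02)
        assert fv.aspect_ratio == pytest.approx(1.5, rel=0.05)
        assert fv.relative_concavity == pytest.approx(0.15, abs=0.02)
        assert fv.autocorrelation_length_scale_um == pytest.approx(0.8, rel=0.15)

    def test_error_names_the_nucleus(self, disk_mask):
        img = NucleusImage(np.zeros(disk_mask.shape), PX)
        with pytest.raises(ValueError, match="nuc-17"):
            ft.extract_features(img, disk_mask, nucleus_id="nuc-17")

    def test_rotation_by_90_degrees_is_exact(self):
        spec = nm.ShapeSpec(area_um2=150, aspect_ratio=1.6, seed=9)
        mask = nm.generate_shape(spec, PX)
        img = nm.generate_texture(mask, nm.TextureSpec(length_scale_um=0.8, seed=10), PX)
        fv = ft.extract_features(img, mask)
        mask90 = NucleusMask(np.rot90(mask.pixels).copy())
        img90 = NucleusImage(np.rot90(img.pixels).copy(), PX)
        fv90 = ft.extract_features(img90, mask90)
        for name in ft.FEATURE_NAMES:
            a, b = getattr(fv, name), getattr(fv90, name)
            if name in ("perimeter_um", "shape_factor"):
                # the smoothed-contour length is rotation-symmetric up to
                # floating-point accumulation order
                assert a == pytest.approx(b, rel=1e-6), name
            else:
                assert a == pytest.approx(b, rel=1e-9), name

    @given(
        a=st.floats(min_value=0.2, max_value=5.0),
        b=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_affine_intensity_invariance(self, a, b, textured_nucleus):
        """Normalized features are invariant under a*I + b (a > 0); the
        centre-centroid mismatch is invariant under pure scaling only."""
        img, mask = textured_nucleus
        fv = ft.extract_features(img, mask)
        rescaled = NucleusImage(a * img.pixels + b, PX)
        fv2 = ft.extract_features(rescaled, mask)
        for name in (
            "projected_area_um2", "aspect_ratio", "perimeter_um", "shape_factor",
            "relative_concavity", "entropy_bits", "sd_normalized_intensities",
            "autocorrelation_length_scale_um",
        ):
            assert getattr(fv, name) == pytest.approx(getattr(fv2, name), rel=1e-6), name
        scaled_only = NucleusImage(a * img.pixels, PX)
        fv3 = ft.extract_features(scaled_only, mask)
        assert fv3.centre_centroid_mismatch_um == pytest.approx(
            fv.centre_centroid_mismatch_um, rel=1e-6
        )
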