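"""Outline geometry: smoothing kernel, normalization, radial sampling, Feret."""

import numpy as np
import pytest

from otoshape.geometry import (
    DegenerateOutlineError,
    feret_diameter,
    feret_dimensions,
    normalize_outline,
    polygon_area,
    profile_to_polygon,
    radial_profile,
    smooth_polygon,
)

from .conftest import ellipse, rotate, star


class TestSmoothing:
    def test_square_corners_forced_by_kernel(self):
        sq = np.array([[1, 1], [-1, 1], [-1, -1], [1, -1]], float)
        out = smooth_polygon(sq, 1)
        np.testing.assert_allclose(out, sq / 2.0)

    def test_collinear_point_is_fixed(self):
        poly = np.array([[0, 0], [1, 0], [2, 0], [2, 2], [0, 2]], float)
        out = smooth_polygon(poly, 1)
        np.testing.assert_allclose(out[1], [1, 0])

    def test_regular_polygon_shrinks_by_closed_form(self):
        n, iters = 256, 100
        t = 2 * np.pi * np.arange(n) / n
        gon = np.stack([np.cos(t), np.sin(t)], axis=1)
        out = smooth_polygon(gon, iters)
        radii = np.hypot(out[:, 0], out[:, 1])
        expected = ((1 + np.cos(2 * np.pi / n)) / 2) ** iters
        np.testing.assert_allclose(radii, expected, rtol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateOutlineError):
            smooth_polygon(np.array([[0.0, 0.0], [1.0, 1.0]]), 1)

    def test_total_curvature_non_increasing(self):
        def turning(poly):
            d = np.roll(poly, -1, axis=0) - poly
            ang = np.arctan2(d[:, 1], d[:, 0])
            ext = np.angle(np.exp(1j * np.diff(np.concatenate([ang, ang[:1]]))))
            return np.abs(ext).sum()

        poly = star(3, n=512)
        poly += np.random.default_rng(0).normal(0, 0.004, poly.shape)
        prev = turning(poly)
        for _ in range(20):
            poly = smooth_polygon(poly, 1)
            cur = turning(poly)
            assert cur <= prev + 1e-9
            prev = cur


class TestNormalize:
    @pytest.mark.parametrize("angle", [0.0, 0.4, 1.3, 2.9])
    def test_ellipse_any_rotation_lands_major_axis_horizontal(self, angle):
        pts = rotate(ellipse(2, 1), angle) + [3.0, -4.0]
        norm = normalize_outline(pts, flip_y=False)
        assert norm.area == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(norm.centroid, 0.0, atol=1e-9)
        _, pa, pb = feret_diameter(norm.points)
        axis_angle = np.arctan2(pb[1] - pa[1], pb[0] - pa[0]) % np.pi
        assert min(axis_angle, np.pi - axis_angle) < 1e-6

    def test_idempotent(self):
        norm = normalize_outline(star(7), flip_y=False)
        again = normalize_outline(norm.points, flip_y=False)
        np.testing.assert_allclose(again.points, norm.points, atol=1e-9)

    def test_scale_invariant(self):
        pts = star(11)
        a = normalize_outline(pts, flip_y=False)
        b = normalize_outline(3.0 * pts, flip_y=False)
        np.testing.assert_allclose(a.points, b.points, atol=1e-9)

    def test_zero_area_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(DegenerateOutlineError):
            normalize_outline(line)


class TestRadialProfile:
    def test_circle_constant_radius(self):
        prof = radial_profile(ellipse(1.5, 1.5, n=4096), 256)
        np.testing.assert_allclose(prof.radii, 1.5, atol=1e-6)

    def test_ellipse_matches_analytic_polar_form(self):
        a, b = 2.0, 1.0
        prof = radial_profile(ellipse(a, b, n=8192), 256)
        theta = 2 * np.pi * np.arange(256) / 256
        analytic = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        np.testing.assert_allclose(prof.radii, analytic, atol=1e-3)

    def test_requested_length_returned(self):
        prof = radial_profile(star(2), 1024)
        assert len(prof) == 1024

    def test_power_of_two_required(self):
        with pytest.raises(ValueError):
            radial_profile(star(2), 1000)

    def test_invariant_under_similarity_after_normalization(self):
        pts = star(5)
        ref = radial_profile(normalize_outline(pts, flip_y=False), 256).radii
        moved = rotate(pts, 1.1) * 4.2 + [10.0, -3.0]
        got = radial_profile(normalize_outline(moved, flip_y=False), 256).radii
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_reconstructed_area_converges_to_one(self):
        norm = normalize_outline(ellipse(2, 1, n=8192), flip_y=False)
        errs = []
        for n in (256, 512, 1024):
            poly = profile_to_polygon(radial_profile(norm, n))
            errs.append(abs(abs(polygon_area(poly)) - 1.0))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-4

    def test_centroid_outside_raises(self):
        # thin horseshoe whose vertex centroid falls in the mouth
        t = np.linspace(0.25 * np.pi, 1.75 * np.pi, 200)
        outer = np.stack([2 * np.cos(t), 2 * np.sin(t)], axis=1)
        inner = np.stack([1.8 * np.cos(t[::-1]), 1.8 * np.sin(t[::-1])], axis=1)
        horseshoe = np.vstack([outer, inner])
        with pytest.raises(DegenerateOutlineError):
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    radial_profile(horseshoe, 64)


class TestFeret:
    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pts = rng.normal(size=(60, 2)) * [3.0, 1.0]
            d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
            oracle = np.sqrt(d2.max())
            length, width = feret_dimensions(pts)
            assert length == pytest.approx(oracle, rel=1e-12)
            assert length >= width > 0

    def test_square_diagonal(self):
        sq = np.array([[0, 0], [200, 0], [200, 200], [0, 200]], float)
        length, width = feret_dimensions(sq)
        assert length == pytest.approx(200 * np.sqrt(2))
        assert width == pytest.approx(200 * np.sqrt(2))
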