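"""Exact polygon section properties against closed forms and the pixel oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribgeom.geometry import (ContourError, DegenerateContourError,
                              InvalidContourError, composite_section_properties,
                              offset_contour, polygon_area_centroid,
                              polygon_second_moments, principal_moments,
                              rasterize_section, validate_contour)
from conftest import (circle_polygon, ellipse_polygon, random_hollow_section,
                      regular_polygon_area)


class TestValidateContour:
    def test_cw_square_normalized_to_ccw(self):
        c = validate_contour([(0, 0), (0, 1), (1, 1), (1, 0)])
        assert c.area == pytest.approx(1.0)
        # CCW orientation: positive signed shoelace area
        pts = c.points
        nxt = np.roll(pts, -1, axis=0)
        assert 0.5 * np.sum(pts[:, 0] * nxt[:, 1] - nxt[:, 0] * pts[:, 1]) > 0

    def test_duplicate_and_closing_vertices_dropped(self):
        c = validate_contour([(0, 0), (1, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert c.n_vertices == 4

    def test_bowtie_rejected(self):
        with pytest.raises(InvalidContourError, match="invalid contour"):
            validate_contour([(0, 0), (2, 2), (2, 0), (0, 2)])

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateContourError, match="degenerate contour"):
            validate_contour([(0, 0), (1, 1)])

    def test_zero_area_rejected(self):
        with pytest.raises(DegenerateContourError, match="degenerate contour"):
            validate_contour([(0, 0), (1, 1), (2, 2)])


class TestAreaCentroid:
    def test_square_side_two_at_origin(self):
        c = validate_contour([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        area, cen = polygon_area_centroid(c)
        assert area == pytest.approx(4.0)
        assert cen == pytest.approx((0.0, 0.0))

    def test_regular_16_gon_closed_form(self):
        r = 3.7
        phi = np.arange(16) * 2 * math.pi / 16
        c = validate_contour(np.stack([r * np.cos(phi), r * np.sin(phi)], 1))
        area, _ = polygon_area_centroid(c)
        assert area == pytest.approx(regular_polygon_area(16, r), rel=1e-12)
        assert area == pytest.approx(3.061467 * r * r, rel=1e-6)

    def test_random_12_gon_matches_pixel_count(self):
        rng = np.random.default_rng(7)
        theta = np.sort(rng.uniform(0, 2 * math.pi, 12))
        r = rng.uniform(3, 6, 12)
        c = validate_contour(np.stack([r * np.cos(theta), r * np.sin(theta)], 1))
        tiny = validate_contour(circle_polygon(1e-3, n=16,
                                               center=c.centroid))
        oracle = rasterize_section(c, tiny, 0.05)
        assert c.area == pytest.approx(oracle.tt_ar, rel=5e-3)


class TestSecondMoments:
    def test_square_about_centroid(self):
        c = validate_contour([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        ixx, iyy, ixy = polygon_second_moments(c, origin=(0, 0))
        assert ixx == pytest.approx(2 * 2 ** 3 / 12)
        assert iyy == pytest.approx(2 * 2 ** 3 / 12)
        assert ixy == pytest.approx(0.0, abs=1e-12)

    def test_solid_ellipse_closed_form(self):
        a, b = 3.0, 1.0
        c = validate_contour(ellipse_polygon(a, b, n=4096))
        ixx, iyy, _ = polygon_second_moments(c, origin=(0, 0))
        assert ixx == pytest.approx(math.pi * a * b ** 3 / 4, rel=1e-5)
        assert iyy == pytest.approx(math.pi * a ** 3 * b / 4, rel=1e-5)

    def test_parallel_axis_shift(self):
        c = validate_contour([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        _, iyy, _ = polygon_second_moments(c, origin=(1.0, 0.0))
        assert iyy == pytest.approx(2 * 2 ** 3 / 12 + 4 * 1.0 ** 2)


class TestCompositeSection:
    def test_circular_annulus_closed_forms(self):
        sp = composite_section_properties(
            validate_contour(circle_polygon(10.0)),
            validate_contour(circle_polygon(8.0)))
        assert sp.tt_ar == pytest.approx(math.pi * 100, rel=1e-5)
        assert sp.es_ar == pytest.approx(math.pi * 64, rel=1e-5)
        assert sp.ct_ar == pytest.approx(math.pi * 36, rel=1e-5)
        exact = math.pi * (10 ** 4 - 8 ** 4) / 4
        assert sp.i_max == pytest.approx(exact, rel=1e-5)
        assert sp.i_min == pytest.approx(exact, rel=1e-5)
        assert sp.i_rat == pytest.approx(0.0, abs=1e-9)

    def test_elliptical_annulus_closed_forms(self):
        sp = composite_section_properties(
            validate_contour(ellipse_polygon(3, 2)),
            validate_contour(ellipse_polygon(2, 1)))
        assert sp.ct_ar == pytest.approx(4 * math.pi, rel=1e-5)
        assert sp.i_min == pytest.approx(math.pi * (3 * 8 - 2 * 1) / 4, rel=1e-5)
        assert sp.i_max == pytest.approx(math.pi * (27 * 2 - 8 * 1) / 4, rel=1e-5)
        assert sp.i_rat == pytest.approx(math.log(46 / 22), rel=1e-5)

    def test_offset_inner_composite_centroid(self):
        # outer R=5 at origin, inner r=2 at (1, 0):
        # x_c = (25*0 - 4*1)/(25 - 4) = -4/21
        sp = composite_section_properties(
            validate_contour(circle_polygon(5.0)),
            validate_contour(circle_polygon(2.0, center=(1.0, 0.0))))
        assert sp.centroid[0] == pytest.approx(-4 / 21, rel=1e-6)
        assert sp.centroid[1] == pytest.approx(0.0, abs=1e-9)
        oracle = rasterize_section(
            validate_contour(circle_polygon(5.0, n=512)),
            validate_contour(circle_polygon(2.0, n=512, center=(1.0, 0.0))),
            0.02)
        assert sp.i_max == pytest.approx(oracle.i_max, rel=5e-3)
        assert sp.i_min == pytest.approx(oracle.i_min, rel=5e-3)

    def test_rectangle_aspect_law(self):
        # hollow rectangle with similar inner: Imax/Imin = (w/h)^2
        w, h, s = 6.0, 2.0, 0.6
        outer = validate_contour([(-w / 2, -h / 2), (w / 2, -h / 2),
                                  (w / 2, h / 2), (-w / 2, h / 2)])
        inner = outer.transformed(scale=s)
        sp = composite_section_properties(outer, inner)
        assert sp.i_rat == pytest.approx(2 * math.log(w / h), rel=1e-12)

    def test_nesting_violations_rejected(self):
        outer = validate_contour(circle_polygon(5.0, n=64))
        crossing = validate_contour(circle_polygon(2.0, n=64, center=(4.0, 0)))
        with pytest.raises(ContourError, match="intersect"):
            composite_section_properties(outer, crossing)
        outside = validate_contour(circle_polygon(1.0, n=64, center=(10.0, 0)))
        with pytest.raises(ContourError, match="outside"):
            composite_section_properties(outer, outside)


class TestOffsetContour:
    def test_circle_dilation_ratio(self):
        c = validate_contour(circle_polygon(5.0))
        d = offset_contour(c, 0.42)
        assert d.area / c.area == pytest.approx((5.42 / 5) ** 2, rel=1e-9)

    def test_zero_offset_is_identity(self):
        c = validate_contour(circle_polygon(3.0, n=64))
        assert np.array_equal(offset_contour(c, 0.0).points, c.points)

    def test_smooth_convex_contour_minkowski_formula(self):
        # vertex-normal offsetting matches the Minkowski dilation area
        # delta*P + pi*delta^2 once corners are shallow (smooth contour);
        # sharp corners deviate by O(1 - cos(half exterior angle))
        rng = np.random.default_rng(3)
        theta = np.arange(48) * 2 * math.pi / 48
        r = 4.0 + 0.5 * np.cos(2 * theta) + 0.2 * np.sin(3 * theta)
        c = validate_contour(np.stack([r * np.cos(theta), r * np.sin(theta)], 1))
        delta = 0.3
        gain = offset_contour(c, delta).area - c.area
        predicted = delta * c.perimeter + math.pi * delta ** 2
        assert gain == pytest.approx(predicted, rel=0.01)

    def test_regular_hexagon_offset_exact_vertex_radius(self):
        # by construction a regular n-gon dilates to vertex radius R + delta
        phi = np.arange(6) * 2 * math.pi / 6
        c = validate_contour(np.stack([2 * np.cos(phi), 2 * np.sin(phi)], 1))
        o = offset_contour(c, 0.3)
        assert o.area == pytest.approx(regular_polygon_area(6, 2.3), rel=1e-12)

    def test_erosion_collapse_raises(self):
        c = validate_contour(circle_polygon(1.0, n=64))
        with pytest.raises(ContourError, match="collapses"):
            offset_contour(c, -1.5)


class TestPrincipalDecomposition:
    def test_tie_gives_zero_angle_and_irat(self):
        i_max, i_min, theta = principal_moments(4.0, 4.0, 0.0)
        assert i_max == i_min == 4.0
        assert theta == 0.0

    def test_max_axis_direction_for_tall_section(self):
        # tall rectangle (h > w): Ixx > Iyy, the max-moment axis is x
        outer = validate_contour([(-1, -3), (1, -3), (1, 3), (-1, 3)])
        inner = outer.transformed(scale=0.5)
        sp = composite_section_properties(outer, inner)
        assert sp.theta_max == pytest.approx(0.0, abs=1e-12)


class TestInvarianceProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), angle=st.floats(-math.pi, math.pi),
           tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_rigid_transform_invariance(self, seed, angle, tx, ty):
        rng = np.random.default_rng(seed)
        outer, inner = random_hollow_section(rng, n=128)
        sp0 = composite_section_properties(outer, inner)
        sp1 = composite_section_properties(
            outer.transformed(rotation=angle, translation=(tx, ty)),
            inner.transformed(rotation=angle, translation=(tx, ty)))
        for attr in ("tt_ar", "ct_ar", "es_ar", "i_max", "i_min"):
            assert getattr(sp1, attr) == pytest.approx(getattr(sp0, attr),
                                                       rel=1e-9)
        assert sp1.i_rat == pytest.approx(sp0.i_rat, rel=1e-9, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), scale=st.floats(0.2, 5.0))
    def test_similarity_scaling_laws(self, seed, scale):
        rng = np.random.default_rng(seed)
        outer, inner = random_hollow_section(rng, n=128)
        sp0 = composite_section_properties(outer, inner)
        sp1 = composite_section_properties(outer.transformed(scale=scale),
                                           inner.transformed(scale=scale))
        for attr in ("tt_ar", "ct_ar", "es_ar"):
            assert getattr(sp1, attr) == pytest.approx(
                getattr(sp0, attr) * scale ** 2, rel=1e-9)
        for attr in ("i_max", "i_min"):
            assert getattr(sp1, attr) == pytest.approx(
                getattr(sp0, attr) * scale ** 4, rel=1e-9)
        assert sp1.i_rat == pytest.approx(sp0.i_rat, rel=1e-9, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_area_additivity(self, seed):
        rng = np.random.default_rng(seed)
        outer, inner = random_hollow_section(rng, n=128)
        sp = composite_section_properties(outer, inner)
        assert sp.tt_ar == pytest.approx(sp.ct_ar + sp.es_ar, rel=1e-9)
        assert sp.i_max >= sp.i_min > 0
        assert sp.i_rat >= 0


class TestRasterOracle:
    def test_annulus_cortical_area(self):
        oracle = rasterize_section(validate_contour(circle_polygon(10.0, n=512)),
                                   validate_contour(circle_polygon(8.0, n=512)),
                                   0.05)
        assert oracle.ct_ar == pytest.approx(113.097, rel=5e-3)

    def test_vanishing_ring_limit(self):
        oracle = rasterize_section(
            validate_contour(circle_polygon(5.0, n=256)),
            validate_contour(circle_polygon(4.999, n=256)), 0.05)
        assert oracle.ct_ar < 1.0

    def test_matches_exact_on_random_sections(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            outer, inner = random_hollow_section(rng, n=256, min_aspect=1.4)
            sp = composite_section_properties(outer, inner)
            oracle = rasterize_section(outer, inner, 0.05)
            for attr in ("tt_ar", "ct_ar", "es_ar", "i_max", "i_min"):
                assert getattr(sp, attr) == pytest.approx(
                    getattr(oracle, attr), rel=5e-3)
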