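"""Lumen morphometrics: closed-form checks, oracle comparisons, and the
isoperimetric / scaling invariants of the shape index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from cuffmap import geometry as geo
from cuffmap import synthetic as syn
from cuffmap.types import CuffSpec, DepthMap


def regular_polygon(n, r=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def ellipse_polygon(a, b, n=4096):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])


def star_polygon(rng, n=24, r_lo=10.0, r_hi=50.0):
    """Random star-shaped polygon: always simple."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    while np.min(np.diff(th)) < 1e-3:
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(r_lo, r_hi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestSampleCrossSections:
    def test_station_count_cylinder(self):
        geom = syn.cuff_bore_geometry(CuffSpec(length=100.0,
                                               wide_diameter=500,
                                               narrow_diameter=499),
                                      spacing=10.0)
        out = geo.sample_cross_sections(geom, spacing=5.0)
        assert out.n_stations == 21  # 100/5 + 1

    def test_cylinder_contours_circular(self):
        cuff = CuffSpec(length=200.0, wide_diameter=500, narrow_diameter=499.9)
        out = geo.sample_cross_sections(syn.cuff_bore_geometry(cuff, 20.0), 5.0)
        for c in out.contours:
            r = np.linalg.norm(c, axis=1)
            assert np.ptp(r) < 0.5

    def test_cuffed_geometry_min_at_narrow_end(self):
        geom, truth = syn.gen_lumen_geometry(CuffSpec())
        out = geo.sample_cross_sections(geom, spacing=5.0)
        m = geo.geometry_metrics(out)
        s_min = m["s_um"][m["equiv_diameter_um"].idxmin()]
        # narrow end at x=0, i.e. s = 3000 for the default [-3000, 3000] extent
        assert abs(s_min - 3000.0) <= out.station_spacing

    def test_degenerate_centerline_rejected(self):
        geom, _ = syn.gen_lumen_geometry(CuffSpec(), n_stations=11)
        geom.centerline[3] = geom.centerline[2]
        with pytest.raises(ValueError, match="degenerate"):
            geo.sample_cross_sections(geom)


class TestContourMetrics:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        m = geo.contour_metrics(sq)
        assert m.area == pytest.approx(1.0)
        assert m.perimeter == pytest.approx(4.0)

    def test_orientation_independent(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        m = geo.contour_metrics(sq[::-1])
        assert m.area == pytest.approx(1.0)

    def test_high_resolution_circle_area(self):
        """Regular 4096-gon of radius 250 µm: area within 1e-5 relative of
        pi * 250^2 (closed form)."""
        m = geo.contour_metrics(regular_polygon(4096, 250.0))
        assert m.area == pytest.approx(np.pi * 250.0 ** 2, rel=1e-5)

    def test_two_vertices_rejected(self):
        with pytest.raises(ValueError):
            geo.contour_metrics(np.array([[0, 0], [1, 1.0]]))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]])
        with pytest.raises(ValueError):
            geo.contour_metrics(bowtie)


class TestShapeIndex:
    def test_circle_limit_is_one(self):
        m = geo.contour_metrics(regular_polygon(4096, 250.0))
        assert m.shape_index == pytest.approx(1.0, abs=1e-4)

    def test_unit_square_pi_over_four(self):
        assert geo.shape_index(1.0, 4.0) == pytest.approx(np.pi / 4)

    def test_ellipse_sequence_decreases_to_zero(self):
        """Growing aspect ratio at fixed area drives SI monotonically toward
        the line limit 0."""
        area = np.pi * 100.0 ** 2
        sis = []
        for aspect in (1, 10, 100, 1000):
            b = np.sqrt(area / (np.pi * aspect))
            a = aspect * b
            m = geo.contour_metrics(ellipse_polygon(a, b, n=8192))
            sis.append(m.shape_index)
        assert all(x > y for x, y in zip(sis, sis[1:]))
        assert sis[-1] < 0.01

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geo.shape_index(0.0, 1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hst.integers(0, 10_000))
    def test_isoperimetric_bound_random_polygons(self, seed):
        """SI <= 1 for every simple polygon."""
        poly = star_polygon(np.random.default_rng(seed))
        assert geo.contour_metrics(poly).shape_index <= 1.0

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hst.integers(0, 10_000),
           hst.floats(0.1, 50.0, allow_nan=False))
    def test_scale_invariance(self, seed, scale):
        poly = star_polygon(np.random.default_rng(seed))
        m1 = geo.contour_metrics(poly)
        m2 = geo.contour_metrics(poly * scale)
        assert m2.shape_index == pytest.approx(m1.shape_index, rel=1e-9)
        assert m2.area == pytest.approx(m1.area * scale ** 2, rel=1e-9)
        assert m2.perimeter == pytest.approx(m1.perimeter * scale, rel=1e-9)


def grid_inscribed_oracle(poly, resolution=1.0):
    """Brute-force maximum inscribed circle: exhaustive search over a regular
    grid of interior points for the one farthest from the polygon boundary
    (exact point-to-boundary distances).  Underestimates the true radius by at
    most half a grid-cell diagonal."""
    import shapely
    from shapely.geometry import Polygon

    p = Polygon(poly)
    minx, miny, maxx, maxy = p.bounds
    xs = np.arange(minx, maxx + resolution, resolution)
    ys = np.arange(miny, maxy + resolution, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts_xy = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(p, pts_xy[:, 0], pts_xy[:, 1])
    pts = shapely.points(pts_xy[inside])
    return shapely.distance(pts, p.boundary).max()


class TestMaxInscribedCircle:
    def test_circle(self):
        _, r = geo.max_inscribed_circle(regular_polygon(512, 250.0), 1.0)
        assert r == pytest.approx(250.0, abs=1.0)

    def test_ellipse_gives_semi_minor(self):
        _, r = geo.max_inscribed_circle(ellipse_polygon(500.0, 250.0), 1.0)
        assert r == pytest.approx(250.0, abs=1.0)

    def test_r_inscribed_below_equivalent_radius(self, rng):
        for _ in range(5):
            poly = star_polygon(rng)
            m = geo.contour_metrics(poly, inscribed=True, resolution=0.5)
            assert m.r_inscribed <= np.sqrt(m.area / np.pi) + 0.5

    def test_random_star_polygons_match_grid_oracle(self, rng):
        """Agreement with the distance-transform oracle within one grid
        cell."""
        for _ in range(8):
            poly = star_polygon(rng)
            _, r = geo.max_inscribed_circle(poly, resolution=0.5)
            r_oracle = grid_inscribed_oracle(poly, resolution=0.5)
            assert abs(r - r_oracle) <= 0.5 + 1e-9


class TestWallThickness:
    def test_parallel_planes(self):
        inner = DepthMap(np.full((4, 5), 10.0), np.zeros((4, 5), bool))
        outer = DepthMap(np.full((4, 5), 50.0), np.zeros((4, 5), bool))
        t, invalid = geo.wall_thickness_map(inner, outer)
        np.testing.assert_allclose(t, 40.0)
        assert not invalid.any()

    def test_generator_pattern_recovered(self, curved_clean_config):
        inner, outer, truth = syn.gen_wall_depth_maps(curved_clean_config, 0)
        t, invalid = geo.wall_thickness_map(inner, outer)
        assert not invalid.any()
        assert np.abs(t - truth).max() <= curved_clean_config.z_spacing

    def test_crossing_surfaces_flagged(self):
        inner = DepthMap(np.full((3, 3), 20.0), np.zeros((3, 3), bool))
        d = np.full((3, 3), 30.0)
        d[1, 1] = 5.0
        outer = DepthMap(d, np.zeros((3, 3), bool))
        t, invalid = geo.wall_thickness_map(inner, outer)
        assert invalid.sum() == 1
        assert np.isnan(t[1, 1])

    def test_misaligned_rejected(self):
        a = DepthMap(np.zeros((3, 3)), np.zeros((3, 3), bool))
        b = DepthMap(np.zeros((4, 3)), np.zeros((4, 3), bool))
        with pytest.raises(ValueError, match="misaligned"):
            geo.wall_thickness_map(a, b)


class TestFitCuff:
    def test_throat_at_generator_narrow_end(self):
        geom, truth = syn.gen_lumen_geometry(CuffSpec())
        placement = geo.fit_cuff(geom, CuffSpec())
        # narrow end at x = 0 -> s = 3000 on the default extent
        assert abs(placement.throat_s - 3000.0) <= geom.station_spacing
        # axis point 1.5 mm upstream for the forward orientation
        assert placement.axis_point[0] == pytest.approx(-1500.0, abs=10.0)

    def test_reversed_orientation_mirrors(self):
        cuff = CuffSpec(orientation="reversed")
        geom, _ = syn.gen_lumen_geometry(cuff)
        placement = geo.fit_cuff(geom, cuff)
        assert placement.axis_point[0] == pytest.approx(1500.0, abs=10.0)

    def test_straight_cylinder_rejected(self):
        geom = syn.cuff_bore_geometry(CuffSpec(length=2000.0,
                                               wide_diameter=500.0,
                                               narrow_diameter=499.99))
        # essentially a cylinder: the minimum sits at the boundary
        with pytest.raises(ValueError, match="stenosis|interior"):
            geo.fit_cuff(geom, CuffSpec(length=100.0))
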