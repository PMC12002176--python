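"""Geometry and polarization-fraction tests, including Monte-Carlo and
rasterization oracles and rigid-motion invariance properties."""

import numpy as np
import pytest
from shapely import contains_xy

from ectopicgc.spatial import (
    CellPoint,
    GCRegion,
    SpatialSample,
    cell_density,
    polarization_fraction,
    region_area,
    region_centroid,
)

from conftest import sample_from_points, star_polygon


def mc_area(region: GCRegion, n: int, rng: np.random.Generator) -> float:
    """Rejection-sampling area oracle."""
    minx, miny, maxx, maxy = region.polygon.bounds
    xs = rng.uniform(minx, maxx, n)
    ys = rng.uniform(miny, maxy, n)
    hits = contains_xy(region.polygon, xs, ys).sum()
    return hits / n * (maxx - minx) * (maxy - miny)


def raster_centroid(region: GCRegion, grid: int = 500) -> tuple[float, float]:
    """Pixel-average centroid oracle on a grid x grid rasterization."""
    minx, miny, maxx, maxy = region.polygon.bounds
    xs = np.linspace(minx, maxx, grid)
    ys = np.linspace(miny, maxy, grid)
    gx, gy = np.meshgrid(xs, ys)
    inside = contains_xy(region.polygon, gx.ravel(), gy.ravel())
    return gx.ravel()[inside].mean(), gy.ravel()[inside].mean()


def bruteforce_fraction(points: np.ndarray, centroid: np.ndarray) -> float:
    """Direct recount of sign(d . (y - c)) over all cells."""
    d = points.mean(axis=0) - centroid
    proj = (points - centroid) @ d
    pos = np.sum(proj > 0) + 0.5 * np.sum(proj == 0)
    return max(pos, len(points) - pos) / len(points)


class TestGeometry:
    def test_unit_square_area_both_orientations(self):
        ccw = GCRegion(((0, 0), (1, 0), (1, 1), (0, 1)))
        cw = GCRegion(((0, 0), (0, 1), (1, 1), (1, 0)))
        assert region_area(ccw) == pytest.approx(1.0)
        assert region_area(cw) == pytest.approx(1.0)

    def test_unit_square_centroid_and_translation(self):
        sq = GCRegion(((0, 0), (1, 0), (1, 1), (0, 1)))
        assert region_centroid(sq) == pytest.approx((0.5, 0.5))
        moved = GCRegion(((10, -3), (11, -3), (11, -2), (10, -2)))
        assert region_centroid(moved) == pytest.approx((10.5, -2.5))

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(ValueError):
            GCRegion(((0, 0), (1, 1)))
        with pytest.raises(ValueError):
            GCRegion(((0, 0), (1, 1), (2, 2)))  # collinear, zero area

    def test_l_shape_centroid_matches_rasterization(self):
        lshape = GCRegion(((0, 0), (2, 0), (2, 1), (1, 1), (1, 3), (0, 3)))
        cx, cy = region_centroid(lshape)
        ox, oy = raster_centroid(lshape, grid=1000)
        diag = np.hypot(2, 3)
        assert abs(cx - ox) < 0.005 * diag
        assert abs(cy - oy) < 0.005 * diag

    def test_random_polygon_area_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        region = star_polygon(rng)
        est = mc_area(region, 400_000, rng)
        assert est == pytest.approx(region_area(region), rel=0.01)


class TestPolarizationFraction:
    def test_equal_split_gives_half(self):
        s = sample_from_points([(2, 1), (2, -1), (-1, 1), (-1, -1)])
        res = polarization_fraction(s, "Tfh", tol=0.0)
        assert res.fraction == 0.5
        assert not res.degenerate

    def test_one_sided_cluster_gives_one(self):
        s = sample_from_points([(5, 0), (6, 0), (5, 1), (6, 1)])
        res = polarization_fraction(s, "Tfh", tol=0.0)
        assert res.fraction == 1.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-8, 8, size=(40, 2))
        base = polarization_fraction(sample_from_points(pts), "Tfh").fraction
        theta = np.deg2rad(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([12.5, -4.0])
        moved_pts = pts @ rot.T + shift
        sq = np.array([(-10, -10), (10, -10), (10, 10), (-10, 10)], float)
        moved_region = GCRegion(tuple(map(tuple, sq @ rot.T + shift)))
        moved = polarization_fraction(
            sample_from_points(moved_pts, region=moved_region), "Tfh").fraction
        assert moved == pytest.approx(base, abs=1e-9)

    def test_single_cell_is_degenerate(self):
        res = polarization_fraction(sample_from_points([(3, 3)]), "Tfh")
        assert res.degenerate and res.fraction == 0.5

    def test_coincident_centroids_are_degenerate(self):
        s = sample_from_points([(1, 0), (-1, 0), (0, 1), (0, -1)])
        res = polarization_fraction(s, "Tfh", tol=1e-9)
        assert res.degenerate and res.fraction == 0.5

    def test_unknown_cell_type_lists_available(self):
        s = sample_from_points([(1, 1)])
        with pytest.raises(ValueError, match="Tfh"):
            polarization_fraction(s, "FDC")

    def test_boundary_cells_split_half_each_side(self):
        # d points along +x; the two cells on the y-axis sit exactly on
        # the splitting line and count half to each side
        s = sample_from_points([(4, 0), (6, 0), (0, 5), (0, -5)])
        res = polarization_fraction(s, "Tfh", tol=1e-9)
        assert res.fraction == pytest.approx(3 / 4)

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(2, 1000))
            pts = rng.uniform(-9, 9, size=(n, 2))
            s = sample_from_points(pts)
            got = polarization_fraction(s, "Tfh").fraction
            assert got == pytest.approx(
                bruteforce_fraction(pts, np.zeros(2)), abs=1e-12)

    def test_range_and_invariance_over_many_point_sets(self):
        """fraction in [0.5, 1] and rigid-motion invariant, 1000 sets."""
        rng = np.random.default_rng(33)
        sq = np.array([(-10, -10), (10, -10), (10, 10), (-10, 10)], float)
        for _ in range(1000):
            n = int(rng.integers(2, 50))
            pts = rng.uniform(-9, 9, size=(n, 2))
            f = polarization_fraction(sample_from_points(pts), "Tfh").fraction
            assert 0.5 <= f <= 1.0
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            shift = rng.uniform(-50, 50, 2)
            region = GCRegion(tuple(map(tuple, sq @ rot.T + shift)))
            f2 = polarization_fraction(
                sample_from_points(pts @ rot.T + shift, region=region),
                "Tfh").fraction
            assert f2 == pytest.approx(f, abs=1e-9)

    def test_one_sided_cluster_rule_constructive(self):
        """All cells within a disk of radius r centered farther than r
        from the region centroid -> fraction exactly 1.0."""
        rng = np.random.default_rng(44)
        for _ in range(50):
            r = rng.uniform(0.5, 3.0)
            direction = rng.normal(size=2)
            direction /= np.hypot(*direction)
            center = direction * rng.uniform(r * 1.05, 8.0)
            n = int(rng.integers(2, 100))
            ang = rng.uniform(0, 2 * np.pi, n)
            rad = r * np.sqrt(rng.uniform(0, 1, n))
            pts = center + np.c_[rad * np.cos(ang), rad * np.sin(ang)]
            f = polarization_fraction(sample_from_points(pts), "Tfh").fraction
            assert f == 1.0

    def test_uniform_null_mean_near_half_and_decreasing_in_n(self):
        """Uniform cells in a disk: mean fraction is slightly above 0.5
        and shrinks toward 0.5 as n grows."""
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        disk = GCRegion(tuple(zip(10 * np.cos(ang), 10 * np.sin(ang))))
        rng = np.random.default_rng(55)

        def mean_fraction(n, sims):
            fracs = []
            for _ in range(sims):
                a = rng.uniform(0, 2 * np.pi, n)
                rad = 10 * np.sqrt(rng.uniform(0, 1, n))
                pts = np.c_[rad * np.cos(a), rad * np.sin(a)]
                s = SpatialSample("d", disk,
                                  [CellPoint(x, y, "t") for x, y in pts])
                fracs.append(polarization_fraction(s, "t").fraction)
            return float(np.mean(fracs))

        m100 = mean_fraction(100, 1000)
        assert 0.5 <= m100 <= 0.56
        m400 = mean_fraction(400, 300)
        assert m400 < m100


class TestDensity:
    def test_count_over_area(self):
        sq = GCRegion(((0, 0), (10, 0), (10, 10), (0, 10)))
        cells = [CellPoint(5, 5, "GCB")] * 10
        s = SpatialSample("g", sq, list(cells))
        res = cell_density(s, "GCB")
        assert res.density == pytest.approx(0.1)

    def test_no_cells_gives_zero_density(self):
        sq = GCRegion(((0, 0), (10, 0), (10, 10), (0, 10)))
        res = cell_density(SpatialSample("g", sq, []), "GCB")
        assert res.density == 0.0

    def test_scaling_law(self):
        sq1 = GCRegion(((0, 0), (10, 0), (10, 10), (0, 10)))
        sq2 = GCRegion(((0, 0), (20, 0), (20, 20), (0, 20)))
        cells1 = [CellPoint(1, 1, "t")] * 8
        cells2 = [CellPoint(2, 2, "t")] * 8
        d1 = cell_density(SpatialSample("a", sq1, cells1), "t").density
        d2 = cell_density(SpatialSample("b", sq2, cells2), "t").density
        assert d2 == pytest.approx(d1 / 4)

    def test_clip_excludes_outside_cells(self):
        sq = GCRegion(((0, 0), (10, 0), (10, 10), (0, 10)))
        cells = [CellPoint(5, 5, "t"), CellPoint(50, 50, "t")]
        s = SpatialSample("g", sq, cells)
        assert cell_density(s, "t", clip=False).n_cells == 2
        assert cell_density(s, "t", clip=True).n_cells == 1
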