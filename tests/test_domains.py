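"""Domain membership, contour digitization, symmetrization, and packing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfbm.domains import (
    CircularObstacle,
    CrowdedDiskDomain,
    DegenerateDomainError,
    PackingError,
    PolarRingDomain,
    RectangleDomain,
    RowIntervalDomain,
    contains,
    digitize_contour,
    place_obstacles,
    read_contour_csv,
    sample_start_position,
    smooth_and_symmetrize,
    write_contour_csv,
)


def circle_polyline(radius, n=2048, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


class TestMembership:
    def test_ring_examples(self, ring):
        # outer radius at phi=0 is 100 * (1 + 0.5) = 150
        assert ring.outer_radius(0.0) == pytest.approx(150.0)
        assert contains(ring, (75.0, 0.0))  # 50 < 75 < 150
        assert not contains(ring, (0.0, 0.0))  # inside the inner hole
        assert contains(ring, (150.0, 0.0))  # allowed region is closed
        assert not contains(ring, (150.01, 0.0))
        # valley direction phi = pi/8 has outer radius 100
        v = (math.cos(math.pi / 8), math.sin(math.pi / 8))
        assert contains(ring, (99.0 * v[0], 99.0 * v[1]))
        assert not contains(ring, (101.0 * v[0], 101.0 * v[1]))

    def test_ring_invalid_geometry(self):
        with pytest.raises(ValueError, match="exceed inner_radius"):
            PolarRingDomain(base_radius=40.0, inner_radius=50.0)

    def test_crowded_disk_obstacles_are_open_forbidden_sets(self):
        obs = CircularObstacle(center=(5.0, 0.0), radius=2.0)
        disk = CrowdedDiskDomain(radius=10.0, obstacles=(obs,))
        assert not contains(disk, (5.0, 0.0))  # obstacle center
        assert contains(disk, (7.0, 0.0))  # obstacle boundary is reachable
        assert contains(disk, (0.0, 0.0))
        assert not contains(disk, (10.5, 0.0))

    def test_obstacle_must_fit_inside_disk(self):
        with pytest.raises(ValueError, match="outside the disk"):
            CrowdedDiskDomain(
                radius=10.0, obstacles=(CircularObstacle((9.5, 0.0), 2.0),)
            )

    def test_contains_many_matches_scalar(self, ring):
        rng = np.random.default_rng(1)
        xs = rng.uniform(-160, 160, 500)
        ys = rng.uniform(-160, 160, 500)
        vec = ring.contains_many(xs, ys)
        scalar = np.array([ring.contains(x, y) for x, y in zip(xs, ys)])
        assert np.array_equal(vec, scalar)

    def test_row_interval_scale_and_rows(self):
        dom = RowIntervalDomain(
            y_min=0, x_left=np.array([0, 0, 0]), x_right=np.array([4, 4, 4]),
            scale=2.0,
        )
        # y=1.2 -> row round(0.6) = 1; x=7 -> 3.5 lattice units, inside
        assert dom.contains(7.0, 1.2)
        assert not dom.contains(9.0, 1.2)  # 4.5 > x_right
        assert not dom.contains(1.0, 6.0)  # row 3 out of range

    def test_row_interval_validation(self):
        with pytest.raises(ValueError, match="x_left > x_right"):
            RowIntervalDomain(
                y_min=0, x_left=np.array([3]), x_right=np.array([1])
            )


class TestDigitizer:
    def test_rectangle_digitizes_exactly(self):
        rect = np.array([[0, 0], [10, 0], [10, 5], [0, 5]], dtype=float)
        dom = digitize_contour(rect, reduction_factor=1)
        assert dom.y_min == 0 and dom.y_max == 5
        assert np.all(dom.x_left == 0)
        assert np.all(dom.x_right == 10)

    def test_circle_agrees_with_point_in_circle_oracle(self):
        dom = digitize_contour(circle_polyline(20.0), reduction_factor=1)
        xs, ys = np.meshgrid(np.arange(-20, 21), np.arange(-20, 21))
        exact = xs**2 + ys**2 <= 400
        dig = dom.contains_many(xs.astype(float), ys.astype(float))
        disagree = exact != dig
        assert disagree.mean() <= 0.01
        if disagree.any():
            dist = np.abs(np.hypot(xs[disagree], ys[disagree]) - 20.0)
            assert dist.max() <= 1.0  # confined to one-cell boundary band

    def test_convex_polygon_matches_scanline_oracle(self):
        """Row intervals equal shapely scanline min/max intersections."""
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import LineString, Polygon

        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(-30, 30, (12, 2))
            hull = pts[_convex_hull_indices(pts)]
            dom = digitize_contour(hull, reduction_factor=1)
            poly = Polygon(hull)
            for row in range(dom.y_min + 1, dom.y_max):  # skip apex rows
                line = LineString([(-100, row), (100, row)])
                seg = poly.intersection(line)
                if seg.is_empty:
                    continue
                lo, hi = seg.bounds[0], seg.bounds[2]
                i = row - dom.y_min
                assert dom.x_left[i] == math.ceil(lo - 1e-6)
                assert dom.x_right[i] == math.floor(hi + 1e-6)

    def test_reduction_round_trip_keeps_membership(self):
        dom1 = digitize_contour(circle_polyline(40.0), reduction_factor=1)
        dom4 = digitize_contour(circle_polyline(40.0), reduction_factor=4)
        xs, ys = np.meshgrid(np.arange(-40, 41, 3), np.arange(-40, 41, 3))
        a = dom1.contains_many(xs.astype(float), ys.astype(float))
        b = dom4.contains_many(xs.astype(float), ys.astype(float))
        # the coarse factor loses at most a thin boundary band
        assert (a == b).mean() > 0.9

    def test_sparse_rows_rejected_with_guidance(self):
        tri = np.array([[0, 0], [40, 0], [20, 30]], dtype=float)
        with pytest.raises(ValueError, match="smaller factor"):
            digitize_contour(tri, reduction_factor=1, resample_spacing=None)

    def test_bad_factor(self):
        with pytest.raises(ValueError, match="positive integer"):
            digitize_contour(circle_polyline(10.0), reduction_factor=0)

    def test_matrix_tsv_round_trip(self, tmp_path):
        dom = digitize_contour(circle_polyline(15.0), reduction_factor=1)
        p = tmp_path / "dom.tsv"
        dom.to_tsv(p, tmp_path / "dom.json")
        back = RowIntervalDomain.from_tsv(p, y_min=dom.y_min)
        assert np.array_equal(back.to_matrix(), dom.to_matrix())


def _convex_hull_indices(pts):
    from scipy.spatial import ConvexHull

    return ConvexHull(pts).vertices


class TestSymmetrize:
    def test_symmetric_input_window_one_is_identity(self):
        # symmetric hexagon starting at the bottom axis crossing, ccw
        hexa = np.array(
            [[0.0, -2.0], [2.0, -1.0], [2.0, 1.0], [0.0, 2.0], [-2.0, 1.0],
             [-2.0, -1.0]]
        )
        out = smooth_and_symmetrize(hexa, window=1, axis_x=0.0)
        assert np.allclose(out, hexa)

    @given(st.integers(min_value=0, max_value=1000), st.integers(1, 7))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_output_exactly_mirror_symmetric(self, seed, window):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        r = 10.0 + rng.normal(0, 0.8, 64)
        poly = np.column_stack([r * np.cos(t) + 1.5, r * np.sin(t)])
        out = smooth_and_symmetrize(poly, window=window, axis_x=1.5)
        mirrored = out.copy()
        mirrored[:, 0] = 3.0 - mirrored[:, 0]
        # identical point sets (compare nearest-neighbour distances)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(out).query(mirrored)
        assert d.max() < 1e-9

    def test_smoothing_reduces_circle_residuals(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        r = 20.0 + rng.normal(0, 0.5, 256)
        noisy = np.column_stack([r * np.cos(t), r * np.sin(t)])

        def residual(poly):
            rad = np.hypot(poly[:, 0], poly[:, 1])
            return np.std(rad)

        rough = smooth_and_symmetrize(noisy, window=1, axis_x=0.0)
        smooth = smooth_and_symmetrize(noisy, window=7, axis_x=0.0)
        assert residual(smooth) <= residual(rough)

    def test_window_too_large(self):
        square = np.array([[0, -1], [1, 0], [0, 1], [-1, 0]], dtype=float)
        with pytest.raises(ValueError, match="window"):
            smooth_and_symmetrize(square, window=5, axis_x=0.0)


class TestPacking:
    def test_reference_packing(self):
        obstacles = place_obstacles(1013, 2.0, 90.0, seed=0)
        assert len(obstacles) == 1013
        centers = np.array([o.center for o in obstacles])
        radii = np.hypot(centers[:, 0], centers[:, 1])
        assert radii.max() <= 88.0 + 1e-9  # fully inside placement radius
        # pairwise non-overlap
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(centers, k=2)
        assert d[:, 1].min() >= 4.0 - 1e-9

    def test_annulus_left_empty(self):
        obstacles = place_obstacles(200, 2.0, 90.0, seed=1)
        disk = CrowdedDiskDomain(radius=100.0, obstacles=tuple(obstacles))
        rng = np.random.default_rng(2)
        phi = rng.uniform(0, 2 * np.pi, 2000)
        r = rng.uniform(90.0, 100.0, 2000)
        ok = disk.contains_many(r * np.cos(phi), r * np.sin(phi))
        assert ok.all()

    def test_deterministic_under_seed(self):
        a = place_obstacles(50, 2.0, 30.0, seed=9)
        b = place_obstacles(50, 2.0, 30.0, seed=9)
        assert all(x.center == y.center for x, y in zip(a, b))

    def test_zero_obstacles(self):
        assert place_obstacles(0, 2.0, 90.0, seed=0) == []

    def test_geometrically_impossible(self):
        with pytest.raises(PackingError):
            place_obstacles(2, 2.0, 2.5, seed=0)


class TestStartSampling:
    def test_postcondition_and_determinism(self, ring):
        rng = np.random.default_rng(5)
        pts = [sample_start_position(ring, rng) for _ in range(50)]
        assert all(contains(ring, p) for p in pts)
        rng2 = np.random.default_rng(5)
        pts2 = [sample_start_position(ring, rng2) for _ in range(50)]
        assert pts == pts2

    def test_uniform_over_disk_quadrants(self, plain_disk):
        from scipy.stats import chisquare

        rng = np.random.default_rng(11)
        pts = np.array([sample_start_position(plain_disk, rng) for _ in range(4000)])
        quad = (pts[:, 0] > 0).astype(int) * 2 + (pts[:, 1] > 0).astype(int)
        counts = np.bincount(quad, minlength=4)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_degenerate_domain_raises(self):
        class Hostile(RectangleDomain):
            def contains_many(self, x, y):
                return np.zeros(np.shape(x), dtype=bool)

        dom = Hostile(0.0, 1.0, 0.0, 1.0)
        with pytest.raises(DegenerateDomainError):
            dom.sample_start(np.random.default_rng(0), max_draws=2048)


def test_contour_csv_round_trip(tmp_path):
    poly = circle_polyline(5.0, n=32)
    p = tmp_path / "contour.csv"
    write_contour_csv(p, poly)
    back = read_contour_csv(p)
    assert np.allclose(back, poly, atol=1e-6)
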