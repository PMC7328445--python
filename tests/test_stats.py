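"""MSD/Hurst estimation, boundary indices, convergence, and uniformity."""

import numpy as np
import pytest

from rfbm.density import DensityGrid
from rfbm.domains import CrowdedDiskDomain, PolarRingDomain, place_obstacles
from rfbm.stats import (
    MSDCurve,
    angular_boundary_profile,
    boundary_accumulation_index,
    compute_msd,
    crowding_report,
    estimate_hurst,
    outer_boundary_distance,
    sector_labels,
    steady_state_distances,
    uniformity_chi_square,
)
from rfbm.walker import grid_geometry, simulate_free


def ring_grid(ring, counts_value=None, cell_size=2.0):
    origin, shape = grid_geometry(ring, cell_size)
    counts = np.zeros(shape, dtype=np.int64)
    if counts_value is not None:
        counts[:] = counts_value
    return DensityGrid(origin=origin, cell_size=cell_size, counts=counts)


class TestMSD:
    def test_ballistic_path_is_exactly_quadratic(self):
        pos = np.column_stack([np.arange(101.0), np.zeros(101)])
        curve = compute_msd([pos], max_lag=20)
        assert np.allclose(curve.msd, curve.lags.astype(float) ** 2)

    def test_matches_direct_average_on_random_path(self, rng):
        pos = rng.normal(0, 1, (64, 2)).cumsum(axis=0)
        curve = compute_msd([pos], max_lag=10)
        for lag in (1, 4, 10):
            direct = np.mean(
                np.sum((pos[lag:] - pos[:-lag]) ** 2, axis=1)
            )
            assert curve.msd[lag - 1] == pytest.approx(direct, rel=1e-10)

    def test_max_lag_bound(self):
        pos = np.zeros((10, 2))
        with pytest.raises(ValueError, match="max_lag"):
            compute_msd([pos], max_lag=10)

    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.8])
    def test_free_fbm_exponent_recovery(self, hurst):
        trajs = simulate_free(hurst, 1.0, 2**13, 16, seed=3)
        curve = compute_msd(trajs, max_lag=1200)
        est = estimate_hurst(curve, (10, 1000))
        assert abs(est - hurst) <= 0.1


class TestHurstEstimate:
    def test_exact_power_laws(self):
        lags = np.arange(1, 2001)
        assert estimate_hurst(
            MSDCurve(lags, lags.astype(float) ** 1.6, 1), (10, 1000)
        ) == pytest.approx(0.8, abs=1e-12)
        assert estimate_hurst(
            MSDCurve(lags, lags.astype(float), 1), (10, 1000)
        ) == pytest.approx(0.5, abs=1e-12)

    def test_non_positive_msd_rejected(self):
        lags = np.arange(1, 100)
        msd = np.ones(99)
        msd[50] = 0.0
        with pytest.raises(ValueError, match="positive"):
            estimate_hurst(MSDCurve(lags, msd, 1), (10, 90))

    def test_empty_range_rejected(self):
        curve = MSDCurve(np.arange(1, 10), np.arange(1.0, 10.0), 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_hurst(curve, (100, 200))


class TestBoundaryIndex:
    def test_uniform_grid_has_unit_index(self, ring):
        grid = ring_grid(ring, counts_value=5)
        report = boundary_accumulation_index(grid, ring, band_width=2.0)
        assert report.index == pytest.approx(1.0)
        assert report.defined

    def test_all_mass_in_band_flags_undefined(self, ring):
        grid = ring_grid(ring)
        dist = outer_boundary_distance(grid, ring)
        cx, cy = grid.center_mesh()
        inside = ring.contains_many(cx, cy)
        band = inside & (dist >= 0) & (dist <= 2.0)
        grid.counts[band] = 9
        report = boundary_accumulation_index(grid, ring, band_width=2.0)
        assert not report.defined
        assert report.index == float("inf")

    def test_bad_band_width(self, ring):
        with pytest.raises(ValueError, match="band_width"):
            boundary_accumulation_index(ring_grid(ring, 1), ring, 0.0)

    def test_report_serialises(self, ring):
        report = boundary_accumulation_index(ring_grid(ring, 2), ring, 2.0)
        d = report.as_dict()
        assert d["defined"] and d["index"] == pytest.approx(1.0)


class TestAngularProfile:
    def test_uniform_grid_flat_profile(self, ring):
        grid = ring_grid(ring, counts_value=3)
        centers, means, nums = angular_boundary_profile(grid, ring, 2.0, 32)
        assert nums.min() > 0
        assert np.allclose(means, 3.0)

    def test_requires_ring(self, ring):
        grid = ring_grid(ring, counts_value=1)
        with pytest.raises(TypeError):
            angular_boundary_profile(grid, CrowdedDiskDomain(10.0), 1.0, 8)


class TestSteadyState:
    def test_identical_maps_zero_distance(self):
        a = np.ones((4, 4), dtype=np.int64)
        mask = np.ones((4, 4), dtype=bool)
        d = steady_state_distances([a, a.copy()], mask)
        assert d[0] == 0.0

    def test_disjoint_maps_distance_one(self):
        a = np.zeros((2, 2), dtype=np.int64)
        b = np.zeros((2, 2), dtype=np.int64)
        a[0, 0] = 7
        b[1, 1] = 3
        mask = np.ones((2, 2), dtype=bool)
        assert steady_state_distances([a, b], mask)[0] == pytest.approx(1.0)

    def test_zero_count_checkpoint_raises(self):
        a = np.zeros((2, 2), dtype=np.int64)
        with pytest.raises(ValueError, match="zero"):
            steady_state_distances([a, a], np.ones((2, 2), dtype=bool))

    def test_needs_two_checkpoints(self):
        a = np.ones((2, 2), dtype=np.int64)
        with pytest.raises(ValueError, match="two checkpoints"):
            steady_state_distances([a], np.ones((2, 2), dtype=bool))

    def test_run_wrapper_reports_distances(self, ring):
        from rfbm.stats import steady_state_check
        from rfbm.walker import SimulationConfig

        cfg = SimulationConfig(
            domain=ring, hurst=0.8, sigma=0.4, n_steps=4096, n_fibers=4,
            seed=8, cell_size=4.0,
        )
        distances, converged = steady_state_check(cfg, (1024, 2048, 4096))
        assert distances.shape == (2,)
        assert np.all(distances >= 0)
        assert converged == bool(np.all(distances < 0.05))


class TestUniformity:
    def test_multinomial_replicates_accept_truth(self, rng):
        frac = np.array([0.4, 0.3, 0.2, 0.1])
        counts = rng.multinomial(5000, frac, size=12)
        res = uniformity_chi_square(counts, frac)
        assert res.p_value > 0.01

    def test_wrong_fractions_rejected(self, rng):
        frac = np.array([0.25, 0.25, 0.25, 0.25])
        skew = np.array([0.55, 0.25, 0.15, 0.05])
        counts = rng.multinomial(5000, skew, size=12)
        res = uniformity_chi_square(counts, frac)
        assert res.p_value < 1e-6

    def test_design_effect_never_inflates(self, rng):
        counts = rng.multinomial(200, [0.5, 0.5], size=30)
        res = uniformity_chi_square(counts, np.array([0.5, 0.5]))
        assert res.design_effect >= 1.0
        assert res.statistic <= res.naive_statistic + 1e-12

    def test_input_validation(self):
        with pytest.raises(ValueError):
            uniformity_chi_square(np.ones((1, 4)), np.full(4, 0.25))
        with pytest.raises(ValueError):
            uniformity_chi_square(np.ones((3, 4)), np.array([0.5, 0.5]))


class TestSectorLabels:
    def test_labels_and_fractions(self, ring):
        grid = ring_grid(ring)
        labels, frac = sector_labels(grid, ring, n_angular=8, n_radial=2)
        assert labels.shape == grid.counts.shape
        assert frac.shape == (16,)
        assert frac.sum() == pytest.approx(1.0)
        cx, cy = grid.center_mesh()
        inside = ring.contains_many(cx, cy)
        assert np.all((labels >= 0) == inside)


class TestCrowding:
    def test_report_classes_and_ratios(self):
        obstacles = place_obstacles(60, 2.0, 25.0, seed=4)
        disk = CrowdedDiskDomain(radius=30.0, obstacles=tuple(obstacles))
        origin, shape = grid_geometry(disk, 1.0)
        counts = np.ones(shape, dtype=np.int64)
        grid = DensityGrid(origin=origin, cell_size=1.0, counts=counts)
        rep = crowding_report(grid, disk, halo_width=1.0)
        # uniform counts: all three class means are 1, both ratios 1
        assert rep["halo_bulk_ratio"] == pytest.approx(1.0)
        assert rep["rim_bulk_ratio"] == pytest.approx(1.0)
        assert min(rep["n_cells"].values()) > 0

    def test_requires_obstacles(self):
        disk = CrowdedDiskDomain(radius=10.0)
        grid = DensityGrid(origin=(-11, -11), cell_size=1.0,
                           counts=np.ones((23, 23), dtype=np.int64))
        with pytest.raises(ValueError, match="no obstacles"):
            crowding_report(grid, disk)
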