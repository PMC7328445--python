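"""Validation statistics for simulated fiber ensembles.

Covers the checks used to certify a run: mean-square displacement and Hurst
recovery on free paths, boundary-accumulation indices and angular boundary
profiles on confined densities, steady-state (run-lengthening) convergence,
replicate-based uniformity testing, and crowding (obstacle halo / outer
rim) summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import chi2

from .density import DensityGrid
from .domains import CrowdedDiskDomain, Domain, PolarRingDomain

__all__ = [
    "MSDCurve",
    "BoundaryIndexReport",
    "UniformityResult",
    "compute_msd",
    "estimate_hurst",
    "boundary_accumulation_index",
    "angular_boundary_profile",
    "steady_state_distances",
    "steady_state_check",
    "uniformity_chi_square",
    "sector_labels",
    "crowding_report",
    "outer_boundary_distance",
]


# ---------------------------------------------------------------------------
# Mean-square displacement and Hurst recovery
# ---------------------------------------------------------------------------


@dataclass
class MSDCurve:
    """Ensemble- and time-origin-averaged mean-square displacement."""

    lags: np.ndarray
    msd: np.ndarray
    n_fibers: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.int64)
        self.msd = np.asarray(self.msd, dtype=float)
        if np.any(self.msd < -1e-9):
            raise ValueError("msd values must be non-negative")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.lags, self.msd]),
            delimiter=",",
            header="lag,msd",
            comments="",
            fmt=["%d", "%.9g"],
        )


def _msd_1d_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-origin-averaged 1D MSD for lags 1..max_lag, O(n log n).

    Uses the standard decomposition msd(m) = S1(m) - 2 S2(m) / (n - m) with
    the autocorrelation S2 computed by FFT; valid because increments are
    stationary, and averaging over all time origins sharply reduces the
    variance compared to displacement-from-start alone.
    """
    n = len(x)
    sq = x * x
    f = np.fft.rfft(x, 2 * n)
    s2 = np.fft.irfft(f * np.conj(f))[:n]
    cs = np.concatenate([[0.0], np.cumsum(sq)])
    total = cs[-1]
    m = np.arange(0, max_lag + 1)
    # Q(m) = sum_{t} x_t^2 + x_{t+m}^2 over valid origins t = 0..n-m-1
    q = (cs[n - m] - 0.0) + (total - cs[m])
    msd = q / (n - m) - 2.0 * s2[: max_lag + 1] / (n - m)
    return msd[1:]


def compute_msd(trajectories, max_lag: int) -> MSDCurve:
    """MSD of free (unreflected) paths, averaged over fibers and time origins.

    ``trajectories`` is a list of (n+1, d) position arrays; the squared
    displacement sums over spatial components.  Intended for unconfined
    paths -- confinement saturates the curve and invalidates exponent fits.
    """
    arrays = [np.asarray(getattr(t, "positions", t), dtype=float) for t in trajectories]
    if not arrays:
        raise ValueError("no trajectories given")
    n_pos = min(len(a) for a in arrays)
    if max_lag >= n_pos:
        raise ValueError(
            f"max_lag={max_lag} must be smaller than the trajectory length {n_pos}"
        )
    acc = np.zeros(max_lag)
    for pos in arrays:
        for d in range(pos.shape[1]):
            acc += _msd_1d_fft(pos[:, d], max_lag)
    return MSDCurve(
        lags=np.arange(1, max_lag + 1), msd=acc / len(arrays), n_fibers=len(arrays)
    )


def estimate_hurst(
    msd: MSDCurve, lag_range: tuple[int, int] = (10, 1000), n_points: int = 64
) -> float:
    """Hurst estimate: half the log-log slope of msd vs lag over ``lag_range``.

    The fit uses ~``n_points`` log-spaced lags so every decade carries equal
    weight.  Raises if the selected MSD values are not strictly positive.
    """
    lo, hi = lag_range
    sel = (msd.lags >= lo) & (msd.lags <= hi)
    if sel.sum() < 2:
        raise ValueError(f"lag_range {lag_range} selects fewer than 2 lags")
    lags = msd.lags[sel].astype(float)
    vals = msd.msd[sel]
    if np.any(vals <= 0):
        raise ValueError("msd must be strictly positive over the fit range")
    idx = np.unique(
        np.clip(
            np.searchsorted(
                lags, np.geomspace(lags[0], lags[-1], n_points)
            ),
            0,
            len(lags) - 1,
        )
    )
    slope = np.polyfit(np.log(lags[idx]), np.log(vals[idx]), 1)[0]
    return float(slope / 2.0)


# ---------------------------------------------------------------------------
# Boundary accumulation
# ---------------------------------------------------------------------------


def outer_boundary_distance(grid: DensityGrid, domain: Domain) -> np.ndarray:
    """Per-cell distance (length units) from cell centers to the outer
    boundary, via a Euclidean distance transform of the outer-contour
    membership mask (inner obstacles ignored).  The transform measures
    center-to-center distances, so half a cell is subtracted to approximate
    the distance to the boundary itself; cells outside the outer contour
    get negative values."""
    cx, cy = grid.center_mesh()
    outer = domain.outer_contains_many(cx, cy)
    dist = (ndimage.distance_transform_edt(outer) - 0.5) * grid.cell_size
    return dist


@dataclass
class BoundaryIndexReport:
    """Ratio of mean density in a boundary band to the interior mean.

    ``index > 1`` signals accumulation at the border (the persistent-walk
    signature); ``index < 1`` depletion (anti-persistent walks).  When the
    interior mean vanishes the index is undefined and flagged rather than
    raised.
    """

    band_width: float
    boundary_mean: float
    interior_mean: float
    index: float
    defined: bool
    n_band_cells: int
    n_interior_cells: int

    def as_dict(self) -> dict:
        return {
            "band_width": self.band_width,
            "boundary_mean": self.boundary_mean,
            "interior_mean": self.interior_mean,
            "index": self.index if self.defined else None,
            "defined": self.defined,
            "n_band_cells": self.n_band_cells,
            "n_interior_cells": self.n_interior_cells,
        }


def boundary_accumulation_index(
    grid: DensityGrid, domain: Domain, band_width: float
) -> BoundaryIndexReport:
    """Mean density within ``band_width`` of the outer boundary over the
    mean density of the remaining in-domain cells."""
    if not band_width > 0:
        raise ValueError("band_width must be positive")
    cx, cy = grid.center_mesh()
    inside = domain.contains_many(cx, cy)
    dist = outer_boundary_distance(grid, domain)
    band = inside & (dist >= 0) & (dist <= band_width)
    interior = inside & (dist > band_width)
    if not band.any() or not interior.any():
        raise ValueError(
            "boundary band or interior is empty; band_width unsuitable for "
            "this grid resolution"
        )
    boundary_mean = float(grid.counts[band].mean())
    interior_mean = float(grid.counts[interior].mean())
    defined = interior_mean > 0
    index = boundary_mean / interior_mean if defined else float("inf")
    return BoundaryIndexReport(
        band_width=float(band_width),
        boundary_mean=boundary_mean,
        interior_mean=interior_mean,
        index=index,
        defined=defined,
        n_band_cells=int(band.sum()),
        n_interior_cells=int(interior.sum()),
    )


def angular_boundary_profile(
    grid: DensityGrid,
    ring: PolarRingDomain,
    band_width: float,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean density in the outer-boundary band, binned by polar angle.

    Returns ``(bin_centers, mean_density, n_cells)``; bins with no cells
    hold NaN means and zero counts.
    """
    if not isinstance(ring, PolarRingDomain):
        raise TypeError("angular profiles require a PolarRingDomain")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    cx, cy = grid.center_mesh()
    inside = ring.contains_many(cx, cy)
    dist = outer_boundary_distance(grid, ring)
    band = inside & (dist >= 0) & (dist <= band_width)
    phi = np.mod(np.arctan2(cy[band], cx[band]), 2.0 * np.pi)
    which = np.minimum((phi / (2.0 * np.pi) * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(which, weights=grid.counts[band].astype(float), minlength=n_bins)
    nums = np.bincount(which, minlength=n_bins)
    means = np.divide(
        sums, nums, out=np.full(n_bins, np.nan), where=nums > 0
    )
    centers = (np.arange(n_bins) + 0.5) * 2.0 * np.pi / n_bins
    return centers, means, nums


# ---------------------------------------------------------------------------
# Steady state and uniformity
# ---------------------------------------------------------------------------


def steady_state_distances(
    checkpoint_counts,
    mask: np.ndarray,
) -> np.ndarray:
    """Half-L1 distances between successive probability-normalised maps.

    ``0.5 * sum_i |p_i - q_i|`` over cells selected by ``mask``; 0 for
    identical maps, 1 for maps with disjoint support.
    """
    maps = []
    for counts in checkpoint_counts:
        vals = np.where(mask, np.asarray(counts, dtype=float), 0.0)
        total = vals.sum()
        if total == 0:
            raise ValueError("a checkpoint map has zero in-domain counts")
        maps.append(vals / total)
    if len(maps) < 2:
        raise ValueError("need at least two checkpoints")
    return np.array(
        [0.5 * np.abs(b - a).sum() for a, b in zip(maps[:-1], maps[1:])]
    )


def steady_state_check(
    config,
    checkpoints,
    threshold: float = 0.05,
):
    """Run an ensemble with nested checkpoints and measure map convergence.

    Checkpoints are step counts (e.g. n and 2n); the same fibers are simply
    run longer, operationalising "the relative densities no longer change
    when the trajectories lengthen".  Returns ``(distances, converged)``
    where ``converged`` is True when every successive half-L1 distance falls
    below ``threshold`` (an artifact convergence criterion, configurable).
    """
    from .walker import run_ensemble  # late import to avoid a cycle

    cps = tuple(int(c) for c in checkpoints)
    if len(cps) < 2:
        raise ValueError("need at least two checkpoints")
    result = run_ensemble(config, checkpoints=cps)
    cx, cy = result.density.center_mesh()
    mask = config.domain.contains_many(cx, cy)
    dists = steady_state_distances(result.checkpoint_counts, mask)
    return dists, bool(np.all(dists < threshold))


@dataclass
class UniformityResult:
    """Design-effect-corrected chi-square test of density uniformity."""

    statistic: float
    dof: int
    p_value: float
    design_effect: float
    naive_statistic: float


def uniformity_chi_square(
    fiber_bin_counts: np.ndarray,
    expected_fractions: np.ndarray,
) -> UniformityResult:
    """Test whether pooled bin occupancies follow ``expected_fractions``.

    Trajectory occupancy counts are heavily autocorrelated (a walker lingers
    near where it has been), so the plain Pearson statistic on pooled counts
    is wildly overdispersed relative to its nominal chi-square law.  Fibers,
    however, are independent replicates: the between-fiber variance of the
    per-bin occupancy shares yields a first-order (Rao-Scott-style) design
    effect by which the naive statistic is deflated before comparison with
    the chi-square(K-1) reference.  The correction is clipped below at 1 so
    an underdispersed estimate can never manufacture significance the plain
    test would not have found.
    """
    counts = np.asarray(fiber_bin_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a (n_fibers >= 2, n_bins) count matrix")
    frac = np.asarray(expected_fractions, dtype=float)
    if frac.shape != (counts.shape[1],) or np.any(frac <= 0):
        raise ValueError("expected_fractions must be positive, one per bin")
    frac = frac / frac.sum()
    m, k = counts.shape
    pooled = counts.sum(axis=0)
    total = pooled.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    p_hat = pooled / total
    naive = float(total * np.sum((p_hat - frac) ** 2 / frac))
    shares = counts / counts.sum(axis=1, keepdims=True)
    var_between = shares.var(axis=0, ddof=1) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        deff = var_between * total / (frac * (1.0 - frac))
    design_effect = float(max(np.nanmean(deff), 1.0))
    stat = naive / design_effect
    dof = k - 1
    return UniformityResult(
        statistic=stat,
        dof=dof,
        p_value=float(chi2.sf(stat, dof)),
        design_effect=design_effect,
        naive_statistic=naive,
    )


def sector_labels(
    grid: DensityGrid,
    domain: Domain,
    n_angular: int,
    n_radial: int = 1,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Label in-domain cells by angular sector (and optional radial shell).

    Returns ``(labels, expected_fractions)`` where ``labels`` has the grid's
    shape (-1 outside the domain) and the expected fraction of each label is
    proportional to its cell count (i.e. its area), the uniform reference.
    """
    cx, cy = grid.center_mesh()
    inside = domain.contains_many(cx, cy)
    phi = np.mod(np.arctan2(cy - center[1], cx - center[0]), 2.0 * np.pi)
    a = np.minimum((phi / (2.0 * np.pi) * n_angular).astype(int), n_angular - 1)
    labels = np.where(inside, a, -1)
    if n_radial > 1:
        r = np.hypot(cx - center[0], cy - center[1])
        r_in = r[inside]
        edges = np.quantile(r_in, np.linspace(0, 1, n_radial + 1))
        shell = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_radial - 1)
        labels = np.where(inside, a * n_radial + shell, -1)
    n_labels = n_angular * max(n_radial, 1)
    areas = np.bincount(labels[labels >= 0], minlength=n_labels).astype(float)
    if np.any(areas == 0):
        raise ValueError("a sector contains no in-domain cells; reduce n_angular")
    return labels, areas / areas.sum()


# ---------------------------------------------------------------------------
# Crowding summaries
# ---------------------------------------------------------------------------


def crowding_report(
    grid: DensityGrid,
    domain: CrowdedDiskDomain,
    halo_width: float = 1.0,
    rim_inner_radius: float | None = None,
    bulk_margin: float | None = None,
) -> dict:
    """Obstacle-halo and outer-rim density summary for a crowded disk.

    Cell classes (centers, in-domain only):

    * ``halo``: within ``halo_width`` of an obstacle boundary,
    * ``rim``: radius between ``rim_inner_radius`` (default: the obstacle
      placement limit) and the disk radius,
    * ``bulk``: interior cells away from obstacles (gap > ``bulk_margin``,
      default equal to ``halo_width`` so bulk is the halo's complement) and
      below the rim.

    Returns mean densities and the halo/bulk, rim/bulk ratios that quantify
    thin high-density layers around obstacles and accumulation at the
    outer border.
    """
    if not isinstance(domain, CrowdedDiskDomain):
        raise TypeError("crowding_report requires a CrowdedDiskDomain")
    if not domain.obstacles:
        raise ValueError("domain has no obstacles")
    cx, cy = grid.center_mesh()
    inside = domain.contains_many(cx, cy)
    r = np.hypot(cx, cy)
    centers = np.array([o.center for o in domain.obstacles])
    radii = np.array([o.radius for o in domain.obstacles])
    if rim_inner_radius is None:
        rim_inner_radius = float(np.max(np.hypot(*centers.T) + radii))
    if bulk_margin is None:
        bulk_margin = halo_width
    tree = cKDTree(centers)
    dist_center, idx = tree.query(np.column_stack([cx.ravel(), cy.ravel()]))
    gap = (dist_center - radii[idx]).reshape(cx.shape)
    halo = inside & (gap >= 0) & (gap <= halo_width) & (r < rim_inner_radius)
    rim = inside & (r >= rim_inner_radius)
    bulk = inside & (gap > bulk_margin) & (r < rim_inner_radius)
    if not (halo.any() and rim.any() and bulk.any()):
        raise ValueError("halo, rim, or bulk cell class is empty")
    halo_mean = float(grid.counts[halo].mean())
    rim_mean = float(grid.counts[rim].mean())
    bulk_mean = float(grid.counts[bulk].mean())
    return {
        "halo_mean": halo_mean,
        "rim_mean": rim_mean,
        "bulk_mean": bulk_mean,
        "halo_bulk_ratio": halo_mean / bulk_mean if bulk_mean > 0 else float("inf"),
        "rim_bulk_ratio": rim_mean / bulk_mean if bulk_mean > 0 else float("inf"),
        "n_cells": {
            "halo": int(halo.sum()),
            "rim": int(rim.sum()),
            "bulk": int(bulk.sum()),
        },
    }
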