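"""Reflected-walk propagation of fibers inside a bounded domain.

A fiber is the path of a discrete 2D walk ``r_{n+1} = r_n + xi_n`` whose
two noise components are independent fGn series with common Hurst index and
step size.  The boundary rule is *rejected steps*: a proposal landing in
the forbidden region is simply not carried out -- the walker keeps its
position, and the increment is consumed (never resampled, which would
distort the prescribed correlation structure).  Acceptance is decided on
the joint 2D proposal: a diagonal step into a corner is wholly rejected.

Ensembles draw per-fiber noise and start positions from sub-streams spawned
deterministically from a master seed, so results are reproducible and
independent of execution order, and density grids are accumulated fiber by
fiber without retaining all trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .density import DensityGrid
from .domains import (
    CircularObstacle,
    CrowdedDiskDomain,
    Domain,
    PolarRingDomain,
    RectangleDomain,
    RowIntervalDomain,
)
from .fgn import FGNSeries, NoiseParams, generate_fgn

__all__ = [
    "Trajectory",
    "SimulationConfig",
    "EnsembleResult",
    "simulate_fiber",
    "run_ensemble",
    "simulate_free",
    "default_step_size",
    "grid_geometry",
]


def default_step_size(hurst: float, base: float = 0.4) -> float:
    """Default per-step standard deviation for confined runs, domain units.

    Anti-persistent walks (H < 1/2) explore so slowly that reaching the
    stationary density within practical run lengths requires a larger step;
    the step size is therefore raised to 1 domain unit in that regime.
    """
    return 1.0 if hurst < 0.5 else base


@dataclass
class Trajectory:
    """Ordered positions of one simulated fiber (all inside the domain)."""

    positions: np.ndarray  # (n_steps + 1, 2)
    accepted: np.ndarray  # (n_steps,) bool; False = rejected (stayed put)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n+1, 2) array")
        if len(self.accepted) != len(self.positions) - 1:
            raise ValueError("accepted flags must have length n_steps")

    @property
    def start(self) -> tuple[float, float]:
        return (float(self.positions[0, 0]), float(self.positions[0, 1]))

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    @property
    def rejection_rate(self) -> float:
        if len(self.accepted) == 0:
            return 0.0
        return float(1.0 - self.accepted.mean())

    def to_csv(self, path) -> None:
        """CSV export with columns step, x, y, accepted (step 0 is the start)."""
        n = len(self.positions)
        acc = np.concatenate([[1], self.accepted.astype(int)])
        table = np.column_stack(
            [np.arange(n), self.positions[:, 0], self.positions[:, 1], acc]
        )
        np.savetxt(
            path,
            table,
            delimiter=",",
            header="step,x,y,accepted",
            comments="",
            fmt=["%d", "%.9g", "%.9g", "%d"],
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a reproducible ensemble run."""

    domain: Domain
    hurst: float
    sigma: float
    n_steps: int
    n_fibers: int
    seed: int
    cell_size: float
    noise_method: str = "circulant"

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie in (0, 1), got {self.hurst}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")


@dataclass
class EnsembleResult:
    """Density grid plus per-fiber bookkeeping from :func:`run_ensemble`."""

    density: DensityGrid
    rejection_rates: np.ndarray
    fiber_spawn_keys: list[int]
    config: SimulationConfig
    checkpoints: tuple[int, ...] = ()
    checkpoint_counts: list[np.ndarray] = field(default_factory=list)
    fiber_bin_counts: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Single-fiber propagation
# ---------------------------------------------------------------------------


def _flatten_rowinterval(domain: RowIntervalDomain):
    cache = getattr(domain, "_kernel_cache", None)
    if cache is not None:
        return cache
    circles = [r for r in domain.inner_regions if isinstance(r, CircularObstacle)]
    rowints = [r for r in domain.inner_regions if isinstance(r, RowIntervalDomain)]
    if len(circles) + len(rowints) != len(domain.inner_regions):
        raise TypeError("inner regions must be CircularObstacle or RowIntervalDomain")
    obs_cx = np.array([c.center[0] for c in circles], dtype=float)
    obs_cy = np.array([c.center[1] for c in circles], dtype=float)
    obs_r2 = np.array([c.radius**2 for c in circles], dtype=float)
    in_off = np.zeros(len(rowints) + 1, dtype=np.int64)
    for k, r in enumerate(rowints):
        in_off[k + 1] = in_off[k] + r.n_rows
    in_ymin = np.array([r.y_min for r in rowints], dtype=np.int64)
    in_scale = np.array([r.scale for r in rowints], dtype=float)
    if rowints:
        in_xl = np.concatenate([r.x_left for r in rowints]).astype(float)
        in_xr = np.concatenate([r.x_right for r in rowints]).astype(float)
    else:
        in_xl = np.empty(0)
        in_xr = np.empty(0)
    cache = (
        int(domain.y_min),
        domain.x_left.astype(float),
        domain.x_right.astype(float),
        float(domain.scale),
        obs_cx,
        obs_cy,
        obs_r2,
        in_off,
        in_ymin,
        in_xl,
        in_xr,
        in_scale,
    )
    object.__setattr__(domain, "_kernel_cache", cache)
    return cache


def _crowded_kernel_args(domain: CrowdedDiskDomain):
    cache = getattr(domain, "_walk_cache", None)
    if cache is not None:
        return cache
    centers = np.array([o.center for o in domain.obstacles], dtype=float).reshape(
        -1, 2
    )
    radii = np.array([o.radius for o in domain.obstacles], dtype=float)
    if len(centers):
        gx0, gy0, cell, nx, ny, start, items = _kernels.build_obstacle_grid(
            centers, radii
        )
    else:
        gx0 = gy0 = 0.0
        cell = 1.0
        nx = ny = 1
        start = np.zeros(2, dtype=np.int64)
        items = np.empty(0, dtype=np.int64)
    cache = (
        float(domain.radius),
        gx0,
        gy0,
        cell,
        nx,
        ny,
        start,
        items,
        centers[:, 0].copy(),
        centers[:, 1].copy(),
        radii**2,
    )
    object.__setattr__(domain, "_walk_cache", cache)
    return cache


def _walk(domain: Domain, x0: float, y0: float, dx: np.ndarray, dy: np.ndarray):
    if isinstance(domain, RectangleDomain):
        return _kernels.walk_rect(
            x0, y0, dx, dy, domain.x_min, domain.x_max, domain.y_min, domain.y_max
        )
    if isinstance(domain, PolarRingDomain) and domain.outer_radius_fn is None:
        return _kernels.walk_ring(
            x0,
            y0,
            dx,
            dy,
            domain.base_radius,
            domain.modulation,
            float(domain.lobe_count),
            domain.inner_radius,
        )
    if isinstance(domain, CrowdedDiskDomain):
        return _kernels.walk_crowded(x0, y0, dx, dy, *_crowded_kernel_args(domain))
    if isinstance(domain, RowIntervalDomain):
        return _kernels.walk_rowinterval(x0, y0, dx, dy, *_flatten_rowinterval(domain))
    return _walk_generic(domain, x0, y0, dx, dy)


def _walk_generic(domain: Domain, x0, y0, dx, dy):
    """Pure-Python fallback for domains without a compiled kernel (slow)."""
    n = len(dx)
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    acc = np.empty(n, dtype=bool)
    x, y = x0, y0
    xs[0], ys[0] = x, y
    for i in range(n):
        px, py = x + dx[i], y + dy[i]
        ok = domain.contains(px, py)
        if ok:
            x, y = px, py
        acc[i] = ok
        xs[i + 1], ys[i + 1] = x, y
    return xs, ys, acc


def simulate_fiber(
    domain: Domain,
    noise_x,
    noise_y,
    start: tuple[float, float],
) -> Trajectory:
    """Advance one fiber through ``domain`` with the rejected-step rule.

    ``noise_x`` / ``noise_y`` are :class:`~rfbm.fgn.FGNSeries` (or plain
    increment arrays) of equal length; ``start`` must lie inside the domain.
    Every emitted position satisfies the membership test; a rejected step
    repeats the previous position and still consumes its increment.
    """
    dx = noise_x.values if isinstance(noise_x, FGNSeries) else np.asarray(noise_x, float)
    dy = noise_y.values if isinstance(noise_y, FGNSeries) else np.asarray(noise_y, float)
    if len(dx) != len(dy):
        raise ValueError("noise_x and noise_y must have the same length")
    x0, y0 = float(start[0]), float(start[1])
    if not domain.contains(x0, y0):
        raise ValueError(f"start position {start} lies outside the domain")
    xs, ys, acc = _walk(domain, x0, y0, dx, dy)
    return Trajectory(positions=np.column_stack([xs, ys]), accepted=acc)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def grid_geometry(
    domain: Domain, cell_size: float
) -> tuple[tuple[float, float], tuple[int, int]]:
    """Origin and (ny, nx) of a grid covering the domain with one pad cell."""
    xmin, ymin, xmax, ymax = domain.bounding_box()
    if not all(map(math.isfinite, (xmin, ymin, xmax, ymax))):
        raise ValueError("ensemble grids require a bounded domain")
    h = cell_size
    origin = (xmin - h, ymin - h)
    nx = int(math.ceil((xmax - origin[0]) / h)) + 2
    ny = int(math.ceil((ymax - origin[1]) / h)) + 2
    return origin, (ny, nx)


def run_ensemble(
    config: SimulationConfig,
    checkpoints: tuple[int, ...] | None = None,
    coarse_labels: np.ndarray | None = None,
) -> EnsembleResult:
    """Simulate ``n_fibers`` independent fibers and accumulate their density.

    Each fiber gets fresh, independent x and y noise series and a uniform
    random start position, all drawn from sub-streams spawned from the
    master seed, so two runs with the same config are identical (the
    density-grid TSV is byte-for-byte reproducible) regardless of order.

    ``checkpoints`` (sorted step counts <= n_steps) additionally record the
    count grid restricted to the first ``c`` steps of every fiber -- the
    run-lengthening convergence probe.  ``coarse_labels`` (an int array of
    the grid's shape, -1 = ignore) collects per-fiber counts over labelled
    cell groups for replicate-based uniformity statistics.
    """
    domain = config.domain
    origin, shape = grid_geometry(domain, config.cell_size)
    counts = np.zeros(shape, dtype=np.int64)
    if checkpoints is not None:
        cps = tuple(int(c) for c in checkpoints)
        if any(c < 1 or c > config.n_steps for c in cps):
            raise ValueError("checkpoints must lie in [1, n_steps]")
        if list(cps) != sorted(set(cps)):
            raise ValueError("checkpoints must be strictly increasing")
    else:
        cps = ()
    ckpt_counts = [np.zeros(shape, dtype=np.int64) for _ in cps]
    n_labels = 0
    fiber_bin_counts = None
    if coarse_labels is not None:
        if coarse_labels.shape != shape:
            raise ValueError(
                f"coarse_labels shape {coarse_labels.shape} does not match "
                f"grid shape {shape}"
            )
        n_labels = int(coarse_labels.max()) + 1
        fiber_bin_counts = np.zeros((config.n_fibers, n_labels), dtype=np.int64)

    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_fibers)
    rejection = np.empty(config.n_fibers)
    ny, nx = shape
    for i, child in enumerate(children):
        ss_x, ss_y, ss_start = child.spawn(3)
        try:
            params = NoiseParams(
                hurst=config.hurst, sigma=config.sigma, n_steps=config.n_steps
            )
            dx = generate_fgn(
                params, method=config.noise_method, rng=np.random.default_rng(ss_x)
            ).values
            dy = generate_fgn(
                params, method=config.noise_method, rng=np.random.default_rng(ss_y)
            ).values
            start = domain.sample_start(np.random.default_rng(ss_start))
            xs, ys, acc = _walk(domain, start[0], start[1], dx, dy)
        except Exception as exc:
            raise RuntimeError(f"fiber {i} failed: {exc}") from exc
        rejection[i] = 1.0 - acc.mean()
        ix = np.floor((xs - origin[0]) / config.cell_size).astype(np.int64)
        iy = np.floor((ys - origin[1]) / config.cell_size).astype(np.int64)
        flat = iy * nx + ix
        counts += np.bincount(flat, minlength=ny * nx).reshape(shape)
        for k, c in enumerate(cps):
            ckpt_counts[k] += np.bincount(
                flat[: c + 1], minlength=ny * nx
            ).reshape(shape)
        if fiber_bin_counts is not None:
            labels = coarse_labels.ravel()[flat]
            good = labels >= 0
            fiber_bin_counts[i] = np.bincount(
                labels[good], minlength=n_labels
            )
    density = DensityGrid(
        origin=origin,
        cell_size=config.cell_size,
        counts=counts,
        n_fibers=config.n_fibers,
        n_steps=config.n_steps,
    )
    return EnsembleResult(
        density=density,
        rejection_rates=rejection,
        fiber_spawn_keys=list(range(config.n_fibers)),
        config=config,
        checkpoints=cps,
        checkpoint_counts=ckpt_counts,
        fiber_bin_counts=fiber_bin_counts,
    )


def simulate_free(
    hurst: float,
    sigma: float,
    n_steps: int,
    n_fibers: int,
    seed: int,
    method: str = "circulant",
) -> list[np.ndarray]:
    """Unconfined 2D FBM paths (cumulative sums of fGn pairs), for MSD checks."""
    master = np.random.SeedSequence(seed)
    out = []
    params = NoiseParams(hurst=hurst, sigma=sigma, n_steps=n_steps)
    for child in master.spawn(n_fibers):
        ss_x, ss_y = child.spawn(2)
        dx = generate_fgn(params, method=method, rng=np.random.default_rng(ss_x)).values
        dy = generate_fgn(params, method=method, rng=np.random.default_rng(ss_y)).values
        pos = np.empty((n_steps + 1, 2))
        pos[0] = 0.0
        np.cumsum(dx, out=pos[1:, 0])
        np.cumsum(dy, out=pos[1:, 1])
        out.append(pos)
    return out
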