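"""Gridded trajectory densities and the optical-density transform.

The simulated density ``d_s`` of a cell is the number of walk positions
falling in it (the start and every post-step position, including the
repeats produced by rejected steps -- an occupancy measure).  Cells are
square, half-open ``[x0 + i h, x0 + (i+1) h) x [y0 + j h, y0 + (j+1) h)``,
anchored at the lower-left ``origin``.

For comparison with immunostained-section images, counts are mapped to
bounded "optical densities" by the Beer-Lambert-like transform
``d_o = 1 - exp(-k d_s)``; the attenuation ``k`` is fitted so the mean
optical value over in-domain cells matches a target mean pixel value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

__all__ = [
    "DensityGrid",
    "OpticalGrid",
    "accumulate",
    "optical_transform",
    "fit_attenuation",
    "density_cut",
    "write_pgm",
]


@dataclass
class DensityGrid:
    """Square-cell occupancy counts over a domain's bounding box.

    ``counts[j, i]`` is the count of the cell whose lower-left corner is
    ``(origin[0] + i * cell_size, origin[1] + j * cell_size)``.
    """

    origin: tuple[float, float]
    cell_size: float
    counts: np.ndarray
    n_fibers: int = 0
    n_steps: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.counts = counts.astype(np.int64, copy=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1D arrays of cell-center x and y coordinates."""
        ny, nx = self.counts.shape
        h = self.cell_size
        xs = self.origin[0] + (np.arange(nx) + 0.5) * h
        ys = self.origin[1] + (np.arange(ny) + 0.5) * h
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = self.cell_centers()
        return np.meshgrid(xs, ys)

    def normalized(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Counts as a probability map (optionally restricted to ``mask``)."""
        vals = self.counts.astype(float)
        if mask is not None:
            vals = np.where(mask, vals, 0.0)
        total = vals.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero density grid")
        return vals / total

    # --- I/O ---------------------------------------------------------------

    def write_tsv(self, path, sidecar_path=None, extra_meta: dict | None = None):
        np.savetxt(path, self.counts, fmt="%d", delimiter="\t")
        if sidecar_path is not None:
            meta = {
                "origin": [float(self.origin[0]), float(self.origin[1])],
                "cell_size": float(self.cell_size),
                "n_fibers": int(self.n_fibers),
                "n_steps": int(self.n_steps),
                "shape": list(self.counts.shape),
            }
            if extra_meta:
                meta.update(extra_meta)
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")

    @classmethod
    def read_tsv(cls, path, sidecar_path) -> "DensityGrid":
        counts = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            origin=tuple(meta["origin"]),
            cell_size=meta["cell_size"],
            counts=counts,
            n_fibers=meta.get("n_fibers", 0),
            n_steps=meta.get("n_steps", 0),
        )


@dataclass
class OpticalGrid:
    """Beer-Lambert-transformed densities, values in [0, 1)."""

    values: np.ndarray
    attenuation: float
    source: DensityGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0) or np.any(vals >= 1.0):
            raise ValueError("optical values must lie in [0, 1)")
        self.values = vals

    @property
    def origin(self):
        return self.source.origin

    @property
    def cell_size(self):
        return self.source.cell_size

    def write_tsv(self, path, sidecar_path=None):
        np.savetxt(path, self.values, fmt="%.9g", delimiter="\t")
        if sidecar_path is not None:
            meta = {
                "origin": [float(self.origin[0]), float(self.origin[1])],
                "cell_size": float(self.cell_size),
                "attenuation": float(self.attenuation),
                "shape": list(self.values.shape),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)
                fh.write("\n")


def bin_positions(
    x: np.ndarray,
    y: np.ndarray,
    origin: tuple[float, float],
    cell_size: float,
    shape: tuple[int, int],
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Accumulate positions into half-open square cells (in-place capable)."""
    ny, nx = shape
    ix = np.floor((x - origin[0]) / cell_size).astype(np.int64)
    iy = np.floor((y - origin[1]) / cell_size).astype(np.int64)
    if ix.min(initial=0) < 0 or iy.min(initial=0) < 0 or (
        ix.size and (ix.max() >= nx or iy.max() >= ny)
    ):
        raise ValueError("position outside the grid extent")
    flat = np.bincount(iy * nx + ix, minlength=ny * nx)
    add = flat.reshape(ny, nx)
    if out is None:
        return add
    out += add
    return out


def accumulate(
    trajectories,
    origin: tuple[float, float],
    cell_size: float,
    shape: tuple[int, int] | None = None,
    on_overflow: str = "extend",
) -> DensityGrid:
    """Bin trajectory positions into a :class:`DensityGrid`.

    ``trajectories`` is an iterable of (n+1, 2) position arrays (or objects
    with a ``positions`` attribute).  Every position, including rejected-step
    repeats, increments its cell.  With ``shape=None`` the grid extent is
    inferred from the data; with a fixed shape, positions outside it either
    grow the grid (``on_overflow="extend"``, shifting the origin by whole
    cells as needed) or raise (``on_overflow="error"``).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if on_overflow not in ("extend", "error"):
        raise ValueError("on_overflow must be 'extend' or 'error'")
    arrays = []
    n_fibers = 0
    n_steps = 0
    for traj in trajectories:
        pos = getattr(traj, "positions", traj)
        pos = np.asarray(pos, dtype=float)
        arrays.append(pos)
        n_fibers += 1
        n_steps = max(n_steps, len(pos) - 1)
    if not arrays:
        raise ValueError("no trajectories given")
    allpos = np.concatenate(arrays, axis=0)
    ix = np.floor((allpos[:, 0] - origin[0]) / cell_size).astype(np.int64)
    iy = np.floor((allpos[:, 1] - origin[1]) / cell_size).astype(np.int64)
    if shape is None:
        lo_x, lo_y = int(ix.min()), int(iy.min())
        hi_x, hi_y = int(ix.max()), int(iy.max())
    else:
        lo_x = lo_y = 0
        hi_y, hi_x = shape[0] - 1, shape[1] - 1
        out = (
            (ix < 0) | (iy < 0) | (ix > hi_x) | (iy > hi_y)
        )
        if np.any(out):
            if on_overflow == "error":
                raise ValueError(
                    f"{int(out.sum())} positions fall outside the fixed grid "
                    "extent"
                )
            lo_x = min(0, int(ix.min()))
            lo_y = min(0, int(iy.min()))
            hi_x = max(hi_x, int(ix.max()))
            hi_y = max(hi_y, int(iy.max()))
    nx = hi_x - lo_x + 1
    ny = hi_y - lo_y + 1
    flat = np.bincount((iy - lo_y) * nx + (ix - lo_x), minlength=ny * nx)
    new_origin = (origin[0] + lo_x * cell_size, origin[1] + lo_y * cell_size)
    return DensityGrid(
        origin=new_origin,
        cell_size=cell_size,
        counts=flat.reshape(ny, nx),
        n_fibers=n_fibers,
        n_steps=n_steps,
    )


def optical_transform(grid: DensityGrid, k: float) -> OpticalGrid:
    """``d_o = 1 - exp(-k d_s)`` elementwise; monotone, zero stays zero."""
    if k < 0:
        raise ValueError(f"attenuation k must be non-negative, got {k}")
    values = -np.expm1(-k * grid.counts.astype(float))
    # the mathematical value is < 1 but floats saturate for large k * d_s
    np.minimum(values, np.nextafter(1.0, 0.0), out=values)
    return OpticalGrid(values=values, attenuation=float(k), source=grid)


def fit_attenuation(
    grid: DensityGrid,
    target_mean: float,
    mask: np.ndarray | None = None,
    tol: float = 1e-9,
) -> float:
    """Attenuation ``k`` whose optical mean over ``mask`` equals ``target_mean``.

    The mean of ``1 - exp(-k d_s)`` is strictly increasing in ``k`` (given at
    least one positive count), so ``k`` is found by bracketing + Brent.  The
    achievable supremum is the fraction of cells with positive counts; a
    target at or above it is infeasible.
    """
    if not (0.0 <= target_mean < 1.0):
        raise ValueError("target_mean must lie in [0, 1)")
    ds = grid.counts[mask].astype(float) if mask is not None else (
        grid.counts.ravel().astype(float)
    )
    if ds.size == 0:
        raise ValueError("mask selects no cells")
    if not np.any(ds > 0):
        raise ValueError("grid has no positive counts; attenuation undefined")
    if target_mean == 0.0:
        return 0.0
    supremum = float(np.mean(ds > 0))
    if target_mean >= supremum - 1e-15:
        raise ValueError(
            f"target_mean {target_mean} is not achievable: the optical mean "
            f"is bounded above by the positive-cell fraction {supremum:.6g}"
        )

    def gap(k: float) -> float:
        return float(np.mean(-np.expm1(-k * ds))) - target_mean

    hi = 1.0 / max(float(ds.mean()), 1e-300)
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e300:  # pragma: no cover - unreachable given supremum check
            raise RuntimeError("failed to bracket attenuation")
    # xtol far below `tol`: the root tolerance bounds the error in k, while
    # the contract bounds the error in the resulting mean
    k = brentq(
        gap, 0.0, hi, xtol=1e-14, rtol=8.881784197001252e-16, maxiter=500
    )
    if abs(gap(k)) > tol:  # pragma: no cover - brentq converges well below tol
        raise RuntimeError(f"attenuation fit residual {gap(k):.3e} exceeds {tol}")
    return float(k)


def density_cut(
    grid,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int,
) -> np.ndarray:
    """Density profile along the segment p0 -> p1.

    Values are sampled at ``n_samples`` evenly spaced points by bilinear
    interpolation of cell-center values; works on either a
    :class:`DensityGrid` (counts) or an :class:`OpticalGrid`.  Both segment
    endpoints must lie within the span of cell centers.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if isinstance(grid, OpticalGrid):
        values = grid.values
        origin, h = grid.origin, grid.cell_size
    else:
        values = grid.counts.astype(float)
        origin, h = grid.origin, grid.cell_size
    ny, nx = values.shape
    xs = origin[0] + (np.arange(nx) + 0.5) * h
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    interp = RegularGridInterpolator(
        (ys, xs), values, method="linear", bounds_error=True
    )
    t = np.linspace(0.0, 1.0, n_samples)
    px = p0[0] + t * (p1[0] - p0[0])
    py = p0[1] + t * (p1[1] - p0[1])
    try:
        return interp(np.column_stack([py, px]))
    except ValueError as exc:
        raise ValueError(
            "density cut exits the grid extent (segment endpoints must lie "
            "within the cell-center span)"
        ) from exc


def write_pgm(path, values: np.ndarray, max_val: int = 65535) -> None:
    """Plain (ASCII, P2) 16-bit PGM export for visual inspection.

    ``values`` are scaled linearly so the array maximum maps to ``max_val``;
    the image row order is flipped so larger y is up.
    """
    arr = np.asarray(values, dtype=float)
    peak = arr.max()
    scaled = np.zeros_like(arr, dtype=np.int64) if peak <= 0 else np.rint(
        arr / peak * max_val
    ).astype(np.int64)
    flipped = scaled[::-1]
    ny, nx = flipped.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{nx} {ny}\n{max_val}\n")
        for row in flipped:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")
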