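"""Bounded 2D regions for reflected-walk simulations.

Three families of domains are supported, mirroring the shapes used to probe
fiber accumulation in brain-like geometry:

* :class:`RowIntervalDomain` -- a digitized closed contour stored as an
  N x 2 integer matrix: for each consecutive integer row (Y) the leftmost
  and rightmost allowed X.  Concavities oriented along the Y axis cannot be
  encoded this way and must be supplied as separate inner contours; inner
  contours (ventricles, white-matter tracts) act as impenetrable obstacles.
* :class:`PolarRingDomain` -- an analytic ring between an inner circle and a
  lobed outer contour ``R_outer(phi) = base * (1 + modulation * cos^2(m phi))``,
  an abstraction of a neural-tube cross-section.
* :class:`CrowdedDiskDomain` -- a disk packed with small circular obstacles
  (cell bodies), leaving an outer rim free, an abstraction of a neocortical
  patch with a soma-free layer I.

Membership convention: the allowed region is closed (its boundary belongs to
it); inner/obstacle regions are open forbidden sets, so obstacle boundaries
remain reachable.  This removes zero-measure ambiguity from the reflection
rule.

Coordinates are continuous and Cartesian.  Analytic shapes are centred on
the origin; digitized shapes live in the coordinate frame of the imported
contour.  Row lookup for continuous positions rounds Y (divided by
``scale``) to the nearest integer row, ties away from zero.
"""

from __future__ import annotations

import abc
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CircularObstacle",
    "Domain",
    "RowIntervalDomain",
    "PolarRingDomain",
    "CrowdedDiskDomain",
    "RectangleDomain",
    "contains",
    "digitize_contour",
    "smooth_and_symmetrize",
    "place_obstacles",
    "sample_start_position",
    "PackingError",
    "DegenerateDomainError",
    "read_contour_csv",
    "write_contour_csv",
]


class PackingError(RuntimeError):
    """Obstacle placement could not be completed within the attempt budget."""


class DegenerateDomainError(RuntimeError):
    """Rejection sampling of start positions fell below the acceptance floor."""


def _round_half_away(values):
    """Round to nearest integer, ties away from zero (symmetric under x -> -x)."""
    arr = np.asarray(values, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    if np.ndim(values) == 0:
        return int(out)
    return out.astype(np.int64)


@dataclass(frozen=True)
class CircularObstacle:
    """An open forbidden disk (e.g. a cell body or a rounded tract section)."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"obstacle radius must be positive, got {self.radius}")

    def forbids(self, x: float, y: float) -> bool:
        dx = x - self.center[0]
        dy = y - self.center[1]
        return dx * dx + dy * dy < self.radius**2

    def forbids_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = x - self.center[0]
        dy = y - self.center[1]
        return dx * dx + dy * dy < self.radius**2


class Domain(abc.ABC):
    """Membership-testable bounded 2D region with forbidden inner regions."""

    @abc.abstractmethod
    def contains(self, x: float, y: float) -> bool:
        """True iff (x, y) is inside the outer boundary and outside every
        inner/obstacle region.  Total: never raises."""

    @abc.abstractmethod
    def outer_contains_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised membership in the outer contour alone (obstacles ignored)."""

    @abc.abstractmethod
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) enclosing the allowed region."""

    def contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.empty(x.shape, dtype=bool)
        flat_x, flat_y, flat_o = x.ravel(), y.ravel(), out.ravel()
        for i in range(flat_x.size):
            flat_o[i] = self.contains(flat_x[i], flat_y[i])
        return out

    def sample_start(
        self,
        rng: np.random.Generator,
        max_draws: int = 200_000,
    ) -> tuple[float, float]:
        """Uniform point in the allowed region by bounding-box rejection."""
        xmin, ymin, xmax, ymax = self.bounding_box()
        block = 512
        drawn = 0
        while drawn < max_draws:
            xs = rng.uniform(xmin, xmax, block)
            ys = rng.uniform(ymin, ymax, block)
            drawn += block
            ok = self.contains_many(xs, ys)
            idx = np.flatnonzero(ok)
            if idx.size:
                i = idx[0]
                return (float(xs[i]), float(ys[i]))
        raise DegenerateDomainError(
            f"no interior point found in {max_draws} draws from the bounding "
            "box; the domain has (near-)zero area"
        )


def contains(domain: Domain, point: Sequence[float]) -> bool:
    """Membership test shared by every domain variant (reflection rule core)."""
    return domain.contains(float(point[0]), float(point[1]))


def sample_start_position(
    domain: Domain,
    rng: np.random.Generator,
    max_draws: int = 200_000,
) -> tuple[float, float]:
    """Uniform start position inside ``domain`` (rejection from bounding box)."""
    return domain.sample_start(rng, max_draws=max_draws)


# ---------------------------------------------------------------------------
# Analytic domains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PolarRingDomain(Domain):
    """Ring between an inner circle and a lobed outer contour.

    The default outer contour ``100 * (1 + 0.5 cos^2(4 phi))`` has eight
    lobes: apices of radius 150 at ``phi = k pi/4`` and valleys of radius
    100 at ``phi = pi/8 + k pi/4``.  ``outer_radius_fn`` may override the
    parametric form with an arbitrary callable (slower simulation path).
    """

    base_radius: float = 100.0
    modulation: float = 0.5
    lobe_count: int = 4
    inner_radius: float = 50.0
    outer_radius_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        if np.any(self.outer_radius(phi) <= self.inner_radius):
            raise ValueError("outer contour must everywhere exceed inner_radius")

    def outer_radius(self, phi):
        if self.outer_radius_fn is not None:
            return self.outer_radius_fn(phi)
        c = np.cos(self.lobe_count * np.asarray(phi, dtype=float))
        return self.base_radius * (1.0 + self.modulation * c * c)

    @property
    def max_outer_radius(self) -> float:
        if self.outer_radius_fn is None:
            return self.base_radius * (1.0 + max(self.modulation, 0.0))
        phi = np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False)
        return float(np.max(self.outer_radius(phi)))

    def contains(self, x: float, y: float) -> bool:
        r = math.hypot(x, y)
        if r < self.inner_radius:
            return False
        return r <= float(self.outer_radius(math.atan2(y, x)))

    def contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        return (r >= self.inner_radius) & (r <= self.outer_radius(np.arctan2(y, x)))

    def outer_contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.hypot(x, y) <= self.outer_radius(np.arctan2(y, x))

    def bounding_box(self) -> tuple[float, float, float, float]:
        r = self.max_outer_radius
        return (-r, -r, r, r)


@dataclass(frozen=True)
class CrowdedDiskDomain(Domain):
    """Disk with impenetrable circular obstacles, every obstacle fully inside."""

    radius: float = 100.0
    obstacles: tuple[CircularObstacle, ...] = ()

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("disk radius must be positive")
        object.__setattr__(self, "obstacles", tuple(self.obstacles))
        for obs in self.obstacles:
            if math.hypot(*obs.center) + obs.radius > self.radius + 1e-9:
                raise ValueError(
                    f"obstacle at {obs.center} (radius {obs.radius}) extends "
                    "outside the disk"
                )

    def _tree(self) -> cKDTree | None:
        if not self.obstacles:
            return None
        tree = getattr(self, "_tree_cache", None)
        if tree is None:
            centers = np.array([o.center for o in self.obstacles])
            tree = cKDTree(centers)
            object.__setattr__(self, "_tree_cache", tree)
        return tree

    def _max_obstacle_radius(self) -> float:
        return max((o.radius for o in self.obstacles), default=0.0)

    def contains(self, x: float, y: float) -> bool:
        if math.hypot(x, y) > self.radius:
            return False
        tree = self._tree()
        if tree is not None:
            r_max = self._max_obstacle_radius()
            for i in tree.query_ball_point([x, y], r_max):
                if self.obstacles[i].forbids(x, y):
                    return False
        return True

    def contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.hypot(x, y) <= self.radius
        tree = self._tree()
        if tree is not None and np.any(ok):
            pts = np.column_stack([x.ravel(), y.ravel()])
            radii = np.array([o.radius for o in self.obstacles])
            if np.allclose(radii, radii[0]):
                dist, _ = tree.query(pts)
                ok = ok & (dist.reshape(x.shape) >= radii[0])
            else:
                forb = np.zeros(pts.shape[0], dtype=bool)
                for obs in self.obstacles:
                    forb |= obs.forbids_many(pts[:, 0], pts[:, 1])
                ok = ok & ~forb.reshape(x.shape)
        return ok

    def outer_contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.hypot(x, y) <= self.radius

    def bounding_box(self) -> tuple[float, float, float, float]:
        r = self.radius
        return (-r, -r, r, r)


@dataclass(frozen=True)
class RectangleDomain(Domain):
    """Axis-aligned box; infinite extents model strips or the free plane."""

    x_min: float = -math.inf
    x_max: float = math.inf
    y_min: float = -math.inf
    y_max: float = math.inf

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("rectangle bounds are inverted")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    outer_contains_many = contains_many

    def bounding_box(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


# ---------------------------------------------------------------------------
# Row-interval (digitized contour) domain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RowIntervalDomain(Domain):
    """Digitized shape: per integer row Y, the allowed X interval.

    ``x_left`` / ``x_right`` are integer arrays over contiguous rows
    ``y_min .. y_min + len - 1`` in lattice units; ``scale`` converts lattice
    units to length units.  ``inner_regions`` are forbidden sub-regions
    (further :class:`RowIntervalDomain` or :class:`CircularObstacle`,
    specified in the same length units).
    """

    y_min: int
    x_left: np.ndarray
    x_right: np.ndarray
    scale: float = 1.0
    inner_regions: tuple = ()

    def __post_init__(self) -> None:
        xl = np.asarray(self.x_left, dtype=np.int64)
        xr = np.asarray(self.x_right, dtype=np.int64)
        if xl.shape != xr.shape or xl.ndim != 1 or xl.size == 0:
            raise ValueError("x_left and x_right must be equal-length 1D arrays")
        if np.any(xl > xr):
            bad = int(np.argmax(xl > xr))
            raise ValueError(
                f"x_left > x_right at row y={self.y_min + bad}"
            )
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "x_left", xl)
        object.__setattr__(self, "x_right", xr)
        object.__setattr__(self, "inner_regions", tuple(self.inner_regions))

    @property
    def y_max(self) -> int:
        return self.y_min + len(self.x_left) - 1

    @property
    def n_rows(self) -> int:
        return len(self.x_left)

    def _in_outer(self, x: float, y: float) -> bool:
        row = _round_half_away(y / self.scale)
        if row < self.y_min or row > self.y_max:
            return False
        i = row - self.y_min
        xx = x / self.scale
        return self.x_left[i] <= xx <= self.x_right[i]

    def _forbidden_by(self, region, x: float, y: float) -> bool:
        if isinstance(region, CircularObstacle):
            return region.forbids(x, y)
        # nested RowIntervalDomain: open in x, rows taken as stored
        row = _round_half_away(y / region.scale)
        if row < region.y_min or row > region.y_max:
            return False
        i = row - region.y_min
        xx = x / region.scale
        return region.x_left[i] < xx < region.x_right[i]

    def contains(self, x: float, y: float) -> bool:
        if not self._in_outer(x, y):
            return False
        for region in self.inner_regions:
            if self._forbidden_by(region, x, y):
                return False
        return True

    def contains_many(self, x, y) -> np.ndarray:
        ok = self.outer_contains_many(x, y)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        for region in self.inner_regions:
            if isinstance(region, CircularObstacle):
                ok &= ~region.forbids_many(x, y)
            else:
                rows = _round_half_away(y / region.scale)
                idx = np.clip(rows - region.y_min, 0, region.n_rows - 1)
                in_rows = (rows >= region.y_min) & (rows <= region.y_max)
                xx = x / region.scale
                forb = in_rows & (xx > region.x_left[idx]) & (xx < region.x_right[idx])
                ok &= ~forb
        return ok

    def outer_contains_many(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rows = _round_half_away(y / self.scale)
        idx = np.clip(rows - self.y_min, 0, self.n_rows - 1)
        xx = x / self.scale
        return (
            (rows >= self.y_min) & (rows <= self.y_max)
            & (xx >= self.x_left[idx]) & (xx <= self.x_right[idx])
        )

    def bounding_box(self) -> tuple[float, float, float, float]:
        s = self.scale
        return (
            float(self.x_left.min() * s),
            float((self.y_min - 0.5) * s),
            float(self.x_right.max() * s),
            float((self.y_max + 0.5) * s),
        )

    def to_matrix(self) -> np.ndarray:
        """The N x 2 integer matrix (x_left, x_right per consecutive row)."""
        return np.column_stack([self.x_left, self.x_right])

    def to_tsv(self, path, sidecar_path=None) -> None:
        """Two-column integer TSV plus an optional JSON sidecar (y_min, scale)."""
        np.savetxt(path, self.to_matrix(), fmt="%d", delimiter="\t")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump({"y_min": int(self.y_min), "scale": self.scale}, fh)

    @classmethod
    def from_tsv(cls, path, y_min: int = 0, scale: float = 1.0) -> "RowIntervalDomain":
        mat = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
        return cls(y_min=y_min, x_left=mat[:, 0], x_right=mat[:, 1], scale=scale)


# ---------------------------------------------------------------------------
# Contour digitization pipeline
# ---------------------------------------------------------------------------


def _close_and_clean(polyline) -> np.ndarray:
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polyline must be an (n, 2) array with n >= 3")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise ValueError("closed polyline needs at least 3 distinct vertices")
    return pts


def _densify(pts: np.ndarray, spacing: float) -> np.ndarray:
    """Insert evenly spaced points along each edge (closed polyline)."""
    out = []
    n = len(pts)
    for i in range(n):
        a = pts[i]
        b = pts[(i + 1) % n]
        seg = np.hypot(*(b - a))
        k = max(1, int(math.ceil(seg / spacing)))
        t = np.arange(k) / k
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.concatenate(out, axis=0)


def _scanline_crossings(pts: np.ndarray, y: float) -> np.ndarray:
    """X-coordinates where the closed polyline meets the horizontal line Y=y."""
    a = pts
    b = np.roll(pts, -1, axis=0)
    ya, yb = a[:, 1], b[:, 1]
    xs = []
    horizontal = (ya == y) & (yb == y)
    if np.any(horizontal):
        xs.append(a[horizontal, 0])
        xs.append(b[horizontal, 0])
    crossing = ((ya - y) * (yb - y) <= 0) & (ya != yb)
    if np.any(crossing):
        t = (y - ya[crossing]) / (yb[crossing] - ya[crossing])
        xs.append(a[crossing, 0] + t * (b[crossing, 0] - a[crossing, 0]))
    if not xs:
        return np.empty(0)
    return np.concatenate(xs)


def digitize_contour(
    polyline,
    reduction_factor: int = 1,
    resample_spacing: float | None | str = "auto",
) -> RowIntervalDomain:
    """Convert a closed contour into a row-interval (N x 2) domain.

    The contour coordinates are divided by ``reduction_factor``, rasterised
    at integer rows, and re-enlarged by the same factor; rows introduced by
    the enlargement are filled by linear interpolation between the nearest
    available rows.  Each reduced row must be supported by at least four
    sampled X-values, otherwise the factor is too coarse for the shape and a
    validation error asks for a smaller one.  Row extremes are taken where
    the (reduced) contour crosses each integer row; a lattice X belongs to
    the row iff it lies inside the crossing interval (center-sampling
    rasterization), so convex shapes reproduce scanline min/max
    intersections and a lattice-aligned circle digitizes essentially
    exactly.

    The contour must be closed, non-self-intersecting, and free of
    concavities along the Y axis (supply such features as separate inner
    contours of the resulting domain).
    """
    factor = int(reduction_factor)
    if factor < 1:
        raise ValueError("reduction_factor must be a positive integer")
    pts = _close_and_clean(polyline)
    if resample_spacing == "auto":
        resample_spacing = 0.25 * factor
    if resample_spacing is not None:
        pts = _densify(pts, float(resample_spacing))
    reduced = pts / factor

    rows_of_pts = _round_half_away(reduced[:, 1])
    y_lo, y_hi = int(rows_of_pts.min()), int(rows_of_pts.max())
    counts = np.bincount(rows_of_pts - y_lo, minlength=y_hi - y_lo + 1)
    if counts.min() < 4:
        bad = int(np.argmin(counts)) + y_lo
        raise ValueError(
            f"reduced row y={bad} is supported by only {int(counts.min())} "
            f"X-values at reduction_factor={factor}; use a smaller factor "
            "(or a denser contour)"
        )

    y_span_lo, y_span_hi = reduced[:, 1].min(), reduced[:, 1].max()
    xl_red = np.empty(y_hi - y_lo + 1, dtype=np.int64)
    xr_red = np.empty_like(xl_red)
    for row in range(y_lo, y_hi + 1):
        if y_span_lo <= row <= y_span_hi:
            xs = _scanline_crossings(reduced, float(row))
        else:
            xs = np.empty(0)
        if xs.size == 0:
            # extreme row rounded up past the contour's actual Y-range:
            # fall back to the sampled points binned into this row
            xs = reduced[rows_of_pts == row, 0]
        # center sampling with a float-fuzz snap; a sliver row without any
        # interior lattice point degenerates to its rounded midpoint
        lo = math.ceil(xs.min() - 1e-6)
        hi = math.floor(xs.max() + 1e-6)
        if lo > hi:
            lo = hi = _round_half_away(0.5 * (xs.min() + xs.max()))
        xl_red[row - y_lo] = lo
        xr_red[row - y_lo] = hi

    # Enlarge back: known rows sit at multiples of the factor; interpolate
    # the rows in between.
    rows_known = np.arange(y_lo, y_hi + 1) * factor
    rows_full = np.arange(y_lo * factor, y_hi * factor + 1)
    xl_full = _round_half_away(np.interp(rows_full, rows_known, xl_red * factor))
    xr_full = _round_half_away(np.interp(rows_full, rows_known, xr_red * factor))
    return RowIntervalDomain(
        y_min=int(y_lo * factor), x_left=xl_full, x_right=xr_full, scale=1.0
    )


def smooth_and_symmetrize(polyline, window: int, axis_x: float) -> np.ndarray:
    """Smooth the right half of a closed contour and mirror it to the left.

    The half of the contour with ``x >= axis_x`` (the median, sagittal line)
    is extracted between its bottom and top axis crossings, smoothed with a
    centred moving average of the given odd-or-even ``window`` (window 1 is
    the identity), pinned to the axis at both ends, and reflected across
    ``x = axis_x``.  The output closed polyline is exactly invariant under
    ``x -> 2 * axis_x - x`` as a point set, compensating small tracing or
    sectioning asymmetries.
    """
    window = int(window)
    if window < 1:
        raise ValueError("window must be a positive integer")
    pts = _close_and_clean(polyline)
    if window > len(pts) // 2:
        raise ValueError(
            f"window {window} exceeds half the vertex count ({len(pts)})"
        )
    # Counterclockwise orientation so the right half runs bottom -> top.
    area2 = np.sum(
        pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1]
    )
    if area2 < 0:
        pts = pts[::-1]

    u = pts[:, 0] - axis_x
    n = len(pts)
    # Insert axis crossings so the polyline has explicit on-axis vertices.
    verts: list[np.ndarray] = []
    on_axis_idx: list[int] = []
    for i in range(n):
        j = (i + 1) % n
        verts.append(pts[i])
        if u[i] == 0.0:
            on_axis_idx.append(len(verts) - 1)
        if (u[i] < 0 < u[j]) or (u[j] < 0 < u[i]):
            t = -u[i] / (u[j] - u[i])
            verts.append(pts[i] + t * (pts[j] - pts[i]))
            on_axis_idx.append(len(verts) - 1)
    if len(on_axis_idx) < 2:
        raise ValueError("contour never crosses the symmetry axis")
    arr = np.array(verts)
    ys_on_axis = arr[on_axis_idx, 1]
    bottom = on_axis_idx[int(np.argmin(ys_on_axis))]
    top = on_axis_idx[int(np.argmax(ys_on_axis))]

    def arc(i0: int, i1: int) -> np.ndarray:
        if i0 <= i1:
            return arr[i0 : i1 + 1]
        return np.concatenate([arr[i0:], arr[: i1 + 1]])

    cand_a = arc(bottom, top)
    cand_b = arc(top, bottom)[::-1]  # also bottom -> top, other side
    right = cand_a if cand_a[:, 0].mean() >= cand_b[:, 0].mean() else cand_b
    right = right.copy()

    if window > 1:
        half = window // 2
        smoothed = right.copy()
        for i in range(1, len(right) - 1):
            lo = max(0, i - half)
            hi = min(len(right), i + half + 1)
            smoothed[i] = right[lo:hi].mean(axis=0)
        right = smoothed
    right[0, 0] = axis_x
    right[-1, 0] = axis_x

    left = right[1:-1][::-1].copy()
    left[:, 0] = 2.0 * axis_x - left[:, 0]
    return np.concatenate([right, left], axis=0)


# ---------------------------------------------------------------------------
# Obstacle packing
# ---------------------------------------------------------------------------


def place_obstacles(
    n: int,
    r_obs: float,
    placement_radius: float,
    seed: int | np.random.Generator | None = None,
    max_attempts: int | None = None,
) -> list[CircularObstacle]:
    """Pack ``n`` equal, non-overlapping disks fully inside ``placement_radius``.

    Random sequential placement: candidate centers are drawn uniformly in
    the disk of radius ``placement_radius - r_obs`` and accepted when at
    least ``2 r_obs`` from every accepted center (touching allowed).
    Deterministic under ``seed``.  Raises :class:`PackingError` when the
    request is geometrically impossible (area bound) or the attempt budget
    runs out near the jamming density.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    if not (r_obs > 0 and placement_radius > 0):
        raise ValueError("r_obs and placement_radius must be positive")
    if placement_radius < r_obs:
        raise PackingError(
            f"placement_radius={placement_radius} cannot fully contain a "
            f"disk of radius {r_obs}"
        )
    # Hexagonal-packing area bound: even a perfect packing of n disks of
    # radius r_obs needs n * pi r^2 <= 0.9069 * pi R^2.
    if n * r_obs**2 > 0.9069 * placement_radius**2:
        raise PackingError(
            f"{n} disks of radius {r_obs} cannot fit inside radius "
            f"{placement_radius} (area bound exceeded)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_attempts is None:
        max_attempts = max(200_000, 500 * n)

    max_center_r = placement_radius - r_obs
    min_sep2 = (2.0 * r_obs) ** 2
    cell = 2.0 * r_obs
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    for _ in range(max_attempts):
        r = max_center_r * math.sqrt(rng.random())
        theta = rng.random() * 2.0 * math.pi
        cx = r * math.cos(theta)
        cy = r * math.sin(theta)
        gi, gj = int(math.floor(cx / cell)), int(math.floor(cy / cell))
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    if (xs[k] - cx) ** 2 + (ys[k] - cy) ** 2 < min_sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        xs[placed], ys[placed] = cx, cy
        grid.setdefault((gi, gj), []).append(placed)
        placed += 1
        if placed == n:
            return [
                CircularObstacle(center=(float(xs[k]), float(ys[k])), radius=r_obs)
                for k in range(n)
            ]
    raise PackingError(
        f"placed only {placed}/{n} obstacles within {max_attempts} attempts; "
        "the requested density is too close to jamming -- raise max_attempts "
        "or lower n"
    )


# ---------------------------------------------------------------------------
# Contour I/O
# ---------------------------------------------------------------------------


def read_contour_csv(path) -> np.ndarray:
    """Read one closed contour as x,y vertex pairs from a plain-text CSV."""
    pts = np.loadtxt(path, delimiter=",", ndmin=2)
    if pts.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (x, y)")
    return pts


def write_contour_csv(path, polyline) -> None:
    np.savetxt(path, np.asarray(polyline, dtype=float), delimiter=",", fmt="%.9g")
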