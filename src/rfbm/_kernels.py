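"""Numba inner loops for the rejected-step reflected walk.

Each kernel advances one walker through a pre-flattened domain description
and records the full position sequence plus per-step acceptance flags.  The
reflection rule is shared: propose ``r + xi``; if the proposal leaves the
allowed region the step is skipped (the walker stays put) but the increment
index still advances, so the prescribed noise correlations are preserved.
Acceptance is decided on the joint 2D proposal, never per component.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "walk_rect",
    "walk_ring",
    "walk_crowded",
    "walk_rowinterval",
    "build_obstacle_grid",
]


@njit(cache=True)
def walk_rect(x0, y0, dx, dy, xmin, xmax, ymin, ymax):
    n = dx.shape[0]
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    acc = np.empty(n, np.bool_)
    x, y = x0, y0
    xs[0] = x
    ys[0] = y
    for i in range(n):
        px = x + dx[i]
        py = y + dy[i]
        ok = (xmin <= px) and (px <= xmax) and (ymin <= py) and (py <= ymax)
        if ok:
            x = px
            y = py
        acc[i] = ok
        xs[i + 1] = x
        ys[i + 1] = y
    return xs, ys, acc


@njit(cache=True)
def walk_ring(x0, y0, dx, dy, base, modulation, lobes, inner):
    n = dx.shape[0]
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    acc = np.empty(n, np.bool_)
    x, y = x0, y0
    xs[0] = x
    ys[0] = y
    inner2 = inner * inner
    for i in range(n):
        px = x + dx[i]
        py = y + dy[i]
        r2 = px * px + py * py
        ok = r2 >= inner2
        if ok:
            c = math.cos(lobes * math.atan2(py, px))
            r_out = base * (1.0 + modulation * c * c)
            ok = r2 <= r_out * r_out
        if ok:
            x = px
            y = py
        acc[i] = ok
        xs[i + 1] = x
        ys[i + 1] = y
    return xs, ys, acc


def build_obstacle_grid(centers: np.ndarray, radii: np.ndarray):
    """CSR neighbour lists for point-in-obstacle queries on a uniform grid.

    Cell size is twice the largest obstacle radius, so any obstacle whose
    open disk can cover a query point has its center within the 3x3 cell
    block around the point.
    """
    r_max = float(radii.max()) if len(radii) else 1.0
    cell = 2.0 * r_max
    gx0 = float(centers[:, 0].min()) - cell if len(centers) else 0.0
    gy0 = float(centers[:, 1].min()) - cell if len(centers) else 0.0
    if len(centers):
        nx = int(np.floor((centers[:, 0].max() - gx0) / cell)) + 2
        ny = int(np.floor((centers[:, 1].max() - gy0) / cell)) + 2
    else:
        nx = ny = 1
    ci = np.floor((centers[:, 0] - gx0) / cell).astype(np.int64)
    cj = np.floor((centers[:, 1] - gy0) / cell).astype(np.int64)
    flat = cj * nx + ci
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    start = np.zeros(nx * ny + 1, dtype=np.int64)
    np.add.at(start, sorted_flat + 1, 1)
    start = np.cumsum(start)
    return (
        float(gx0),
        float(gy0),
        float(cell),
        int(nx),
        int(ny),
        start,
        order.astype(np.int64),
    )


@njit(cache=True)
def _in_obstacle(px, py, gx0, gy0, cell, nx, ny, start, items, cx, cy, r2):
    gi = int(math.floor((px - gx0) / cell))
    gj = int(math.floor((py - gy0) / cell))
    for dj in range(-1, 2):
        j = gj + dj
        if j < 0 or j >= ny:
            continue
        for di in range(-1, 2):
            i = gi + di
            if i < 0 or i >= nx:
                continue
            f = j * nx + i
            for s in range(start[f], start[f + 1]):
                k = items[s]
                ddx = px - cx[k]
                ddy = py - cy[k]
                if ddx * ddx + ddy * ddy < r2[k]:
                    return True
    return False


@njit(cache=True)
def walk_crowded(
    x0, y0, dx, dy, radius, gx0, gy0, cell, nx, ny, start, items, cx, cy, r2
):
    n = dx.shape[0]
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    acc = np.empty(n, np.bool_)
    x, y = x0, y0
    xs[0] = x
    ys[0] = y
    rad2 = radius * radius
    has_obs = cx.shape[0] > 0
    for i in range(n):
        px = x + dx[i]
        py = y + dy[i]
        ok = px * px + py * py <= rad2
        if ok and has_obs:
            ok = not _in_obstacle(
                px, py, gx0, gy0, cell, nx, ny, start, items, cx, cy, r2
            )
        if ok:
            x = px
            y = py
        acc[i] = ok
        xs[i + 1] = x
        ys[i + 1] = y
    return xs, ys, acc


@njit(cache=True)
def _rowint_allows(
    px,
    py,
    y_min,
    xl,
    xr,
    scale,
    obs_cx,
    obs_cy,
    obs_r2,
    in_off,
    in_ymin,
    in_xl,
    in_xr,
    in_scale,
):
    yy = py / scale
    row = int(math.floor(abs(yy) + 0.5))
    if yy < 0:
        row = -row
    idx = row - y_min
    if idx < 0 or idx >= xl.shape[0]:
        return False
    xx = px / scale
    if xx < xl[idx] or xx > xr[idx]:
        return False
    for k in range(obs_cx.shape[0]):
        ddx = px - obs_cx[k]
        ddy = py - obs_cy[k]
        if ddx * ddx + ddy * ddy < obs_r2[k]:
            return False
    for k in range(in_off.shape[0] - 1):
        s = in_scale[k]
        yy2 = py / s
        row2 = int(math.floor(abs(yy2) + 0.5))
        if yy2 < 0:
            row2 = -row2
        j = row2 - in_ymin[k]
        lo = in_off[k]
        if 0 <= j < in_off[k + 1] - lo:
            xx2 = px / s
            if in_xl[lo + j] < xx2 < in_xr[lo + j]:
                return False
    return True


@njit(cache=True)
def walk_rowinterval(
    x0,
    y0,
    dx,
    dy,
    y_min,
    xl,
    xr,
    scale,
    obs_cx,
    obs_cy,
    obs_r2,
    in_off,
    in_ymin,
    in_xl,
    in_xr,
    in_scale,
):
    n = dx.shape[0]
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    acc = np.empty(n, np.bool_)
    x, y = x0, y0
    xs[0] = x
    ys[0] = y
    for i in range(n):
        px = x + dx[i]
        py = y + dy[i]
        ok = _rowint_allows(
            px, py, y_min, xl, xr, scale,
            obs_cx, obs_cy, obs_r2,
            in_off, in_ymin, in_xl, in_xr, in_scale,
        )
        if ok:
            x = px
            y = py
        acc[i] = ok
        xs[i + 1] = x
        ys[i + 1] = y
    return xs, ys, acc
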