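"""Static navigation floor field.

The desired walking direction of every agent is the negative gradient of a
time-cost field c(x) obtained by solving the Eikonal equation |∇c| = F on a
regular grid, with c = 0 on the exit line. The slowness F encodes wall
avoidance: it rises linearly from 1 (free walking) to 1 + g on the walls over
the wall-avoidance distance d_w, so cost-optimal paths keep clearance from
walls without being blocked in narrow passages.

The solver is a first-order fast-marching method (monotone upwind update,
binary-heap front). The field is computed once per geometry and queried by
bilinear interpolation during the simulation.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely

from .geometry import Geometry

logger = logging.getLogger(__name__)

#: sentinel carried by wall / unreachable cells
INF = np.inf


class FloorFieldError(ValueError):
    pass


def build_slowness(
    geometry: Geometry, dh: float, d_w: float = 0.25, g: float = 3.0
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Grid of slowness values F(x) = 1 + g·max(0, 1 − d(x)/d_w).

    Returns ``(F, walkable, x0, y0)`` where ``F`` and the boolean mask
    ``walkable`` are (ny, nx) arrays indexed [iy, ix], and (x0, y0) is the
    coordinate of cell (0, 0). The x-grid is symmetric about x = 0 so that
    mirror-symmetric geometries yield mirror-symmetric fields.
    """
    if dh <= 0:
        raise FloorFieldError("grid spacing must be positive")
    if geometry.w_e / dh < 3:
        raise FloorFieldError(
            f"grid spacing {dh} m too coarse to resolve the {geometry.w_e} m exit"
        )
    half_nx = int(math.ceil((geometry.b / 2.0 + dh) / dh))
    xs = np.arange(-half_nx, half_nx + 1) * dh
    y_lo = -geometry.exit_depth - dh
    y_hi = geometry.l_c + dh
    ys = np.arange(math.floor(y_lo / dh), math.ceil(y_hi / dh) + 1) * dh
    xx, yy = np.meshgrid(xs, ys)
    walkable = shapely.contains_xy(geometry.walkable_polygon, xx.ravel(), yy.ravel())
    walkable = walkable.reshape(xx.shape)
    d = geometry.distance_to_walls(np.column_stack([xx.ravel(), yy.ravel()]))
    d = d.reshape(xx.shape)
    if d_w > 0:
        F = 1.0 + g * np.maximum(0.0, 1.0 - d / d_w)
    else:
        F = np.ones_like(d)
    F[~walkable] = INF
    return F, walkable, float(xs[0]), float(ys[0])


def solve_eikonal(
    F: np.ndarray,
    dh: float,
    targets: list[tuple[int, int]],
    walkable: np.ndarray | None = None,
) -> np.ndarray:
    """First-order fast-marching solution of |∇c| = F with c = 0 on targets.

    ``targets`` are (iy, ix) cell indices. Cells where ``walkable`` is False
    (or F is infinite) keep the infinite sentinel; so do walkable cells that
    the front never reaches (a warning is logged for those).
    """
    ny, nx = F.shape
    if walkable is None:
        walkable = np.isfinite(F)
    if not targets:
        raise FloorFieldError("empty target set")
    cost = np.full((ny, nx), INF)
    accepted = np.zeros((ny, nx), dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for iy, ix in targets:
        if not walkable[iy, ix]:
            raise FloorFieldError(f"target cell ({iy},{ix}) is not walkable")
        cost[iy, ix] = 0.0
        heapq.heappush(heap, (0.0, iy, ix))

    walk = walkable  # local aliases for the hot loop
    c = cost
    push = heapq.heappush
    pop = heapq.heappop
    while heap:
        cv, iy, ix = pop(heap)
        if accepted[iy, ix]:
            continue
        accepted[iy, ix] = True
        for djy, djx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jy, jx = iy + djy, ix + djx
            if jy < 0 or jy >= ny or jx < 0 or jx >= nx:
                continue
            if accepted[jy, jx] or not walk[jy, jx]:
                continue
            # upwind values from accepted neighbours in each axis
            a = INF
            if jx > 0 and accepted[jy, jx - 1]:
                a = c[jy, jx - 1]
            if jx < nx - 1 and accepted[jy, jx + 1] and c[jy, jx + 1] < a:
                a = c[jy, jx + 1]
            bv = INF
            if jy > 0 and accepted[jy - 1, jx]:
                bv = c[jy - 1, jx]
            if jy < ny - 1 and accepted[jy + 1, jx] and c[jy + 1, jx] < bv:
                bv = c[jy + 1, jx]
            f = F[jy, jx] * dh
            if a > bv:
                a, bv = bv, a
            if bv - a >= f:  # one-sided update
                cnew = a + f
            else:
                cnew = 0.5 * (a + bv + math.sqrt(2.0 * f * f - (a - bv) ** 2))
            if cnew < c[jy, jx]:
                c[jy, jx] = cnew
                push(heap, (cnew, jy, jx))

    unreached = walkable & ~accepted
    if unreached.any():
        logger.warning("%d walkable cells unreachable from the target", unreached.sum())
    return cost


@dataclass
class FloorField:
    """Solved navigation field for one geometry.

    Holds the cost grid and precomputed unit desired-direction grids; queries
    are bilinear interpolations, renormalised to unit length.
    """

    geometry: Geometry
    dh: float
    d_w: float
    g: float
    x0: float
    y0: float
    cost: np.ndarray
    slowness: np.ndarray
    walkable: np.ndarray
    ux: np.ndarray
    uy: np.ndarray

    def __post_init__(self) -> None:
        # stencil validity: a query cell is usable if any corner of its
        # bilinear stencil is a walkable cell with finite cost
        valid = self.walkable & np.isfinite(self.cost)
        ok = valid.copy()
        ok[:-1, :] |= valid[1:, :]
        ok[:, :-1] |= valid[:, 1:]
        ok[:-1, :-1] |= valid[1:, 1:]
        self._stencil_ok = ok
        self._uflat = np.ascontiguousarray(self.ux.ravel())
        self._vflat = np.ascontiguousarray(self.uy.ravel())

    @property
    def shape(self) -> tuple[int, int]:
        return self.cost.shape

    def cost_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinearly interpolated time cost at the query points (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        filled = _fill_walls(self.cost, self.walkable, self.dh, self.slowness)
        vals = _bilinear(filled, self.x0, self.y0, self.dh, pts)
        return vals if np.asarray(points).ndim == 2 else float(vals[0])

    def desired_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit desired direction −∇c/|∇c| at each query point.

        Accepts (2,) or (n, 2). Points in wall or unreachable cells raise;
        flat spots fall back to pointing at the exit centre (logged).
        """
        single = np.asarray(points).ndim == 1
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ny, nx = self.shape
        gx = np.clip((pts[:, 0] - self.x0) / self.dh, 0.0, nx - 1.001)
        gy = np.clip((pts[:, 1] - self.y0) / self.dh, 0.0, ny - 1.001)
        ix = gx.astype(int)
        iy = gy.astype(int)
        # points may sit arbitrarily close to walls; only points fully
        # inside walls / unreachable areas raise
        bad = ~self._stencil_ok[iy, ix]
        if bad.any():
            raise FloorFieldError(
                f"{bad.sum()} query point(s) in wall or unreachable cells"
            )
        fx = gx - ix
        fy = gy - iy
        base = iy * nx + ix
        w00 = (1 - fx) * (1 - fy)
        w10 = fx * (1 - fy)
        w01 = (1 - fx) * fy
        w11 = fx * fy
        u, vv = self._uflat, self._vflat
        ex = (
            u[base] * w00 + u[base + 1] * w10 + u[base + nx] * w01
            + u[base + nx + 1] * w11
        )
        ey = (
            vv[base] * w00 + vv[base + 1] * w10 + vv[base + nx] * w01
            + vv[base + nx + 1] * w11
        )
        norm = np.hypot(ex, ey)
        flat = norm < 1e-12
        if flat.any():
            logger.debug("flat floor-field spot at %d points", int(flat.sum()))
            ex[flat] = -pts[flat, 0]
            ey[flat] = -pts[flat, 1]
            norm[flat] = np.hypot(ex[flat], ey[flat])
            still = norm < 1e-12  # the exit centre itself
            ey[still] = -1.0
            norm[still] = 1.0
        out = np.column_stack([ex / norm, ey / norm])
        return out[0] if single else out


def _fill_walls(
    cost: np.ndarray, walkable: np.ndarray, dh: float, slowness: np.ndarray
) -> np.ndarray:
    """Replace wall/unreachable sentinels by a large finite cost.

    Central differences then point the gradient away from walls, which both
    keeps the interpolated direction meaningful in wall-adjacent cells and
    adds a repulsive component consistent with the slowness ramp.
    """
    filled = cost.copy()
    finite = np.isfinite(cost)
    if not finite.any():
        raise FloorFieldError("cost field has no finite values")
    fill_value = cost[finite].max() + 10.0 * dh * np.nanmax(slowness[finite])
    filled[~finite] = fill_value
    return filled


def _bilinear(
    grid: np.ndarray, x0: float, y0: float, dh: float, pts: np.ndarray
) -> np.ndarray:
    ny, nx = grid.shape
    gx = np.clip((pts[:, 0] - x0) / dh, 0.0, nx - 1.001)
    gy = np.clip((pts[:, 1] - y0) / dh, 0.0, ny - 1.001)
    ix = gx.astype(int)
    iy = gy.astype(int)
    fx = gx - ix
    fy = gy - iy
    return (
        grid[iy, ix] * (1 - fx) * (1 - fy)
        + grid[iy, ix + 1] * fx * (1 - fy)
        + grid[iy + 1, ix] * (1 - fx) * fy
        + grid[iy + 1, ix + 1] * fx * fy
    )


def compute_floor_field(
    geometry: Geometry, dh: float = 0.01, d_w: float = 0.25, g: float = 3.0
) -> FloorField:
    """Build slowness, solve the Eikonal equation and prepare direction grids.

    The target domain is the exit line y = 0, |x| ≤ w_e/2, thickened to the
    single grid row nearest y = 0.
    """
    F, walkable, x0, y0 = build_slowness(geometry, dh, d_w, g)
    iy0 = int(round(-y0 / dh))
    xs_idx = np.nonzero(
        (np.abs(x0 + np.arange(F.shape[1]) * dh) <= geometry.w_e / 2.0 + 1e-12)
        & walkable[iy0]
    )[0]
    if len(xs_idx) == 0:
        raise FloorFieldError("no walkable target cells on the exit line")
    targets = [(iy0, int(ix)) for ix in xs_idx]
    cost = solve_eikonal(F, dh, targets, walkable)

    filled = _fill_walls(cost, walkable, dh, F)
    gy_, gx_ = np.gradient(filled, dh)
    norm = np.hypot(gx_, gy_)
    norm[norm < 1e-300] = 1.0
    ux = -gx_ / norm
    uy = -gy_ / norm
    return FloorField(
        geometry=geometry,
        dh=dh,
        d_w=d_w,
        g=g,
        x0=x0,
        y0=y0,
        cost=cost,
        slowness=F,
        walkable=walkable,
        ux=ux,
        uy=uy,
    )
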