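"""Walking domains for bottleneck scenarios.

Two variants are supported, both with the exit centred at the origin and the
corridor extending upstream in +y:

* ``corridor`` — straight corridor of width ``b`` closed at the bottom by two
  horizontal wall stubs that leave a door of width ``w_e`` at ``y = 0``.
* ``hopper``   — the bottom wall stubs are replaced by 45° funnel walls
  running from the door edges up to the side walls.

A short downstream passage of width ``w_e`` below ``y = 0`` lets agents clear
the door line before they are removed, so crossing times can be interpolated.
All lengths are metres; positions are disc centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient


class GeometryError(ValueError):
    """Raised for inconsistent domain dimensions."""


@dataclass(frozen=True)
class MeasurementArea:
    """Axis-aligned rectangle used for density measurement."""

    x_min: float = -0.4
    x_max: float = 0.4
    y_min: float = 0.5
    y_max: float = 1.3

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise GeometryError("measurement area must have positive extent")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def as_polygon(self) -> Polygon:
        return Polygon(
            [
                (self.x_min, self.y_min),
                (self.x_max, self.y_min),
                (self.x_max, self.y_max),
                (self.x_min, self.y_max),
            ]
        )


@dataclass(frozen=True)
class Geometry:
    """A walkable domain with its bounding walls and exit.

    ``wall_segments`` is an (n, 2, 2) float array of line segments lying on
    the boundary of ``walkable_polygon``; the upstream closure at
    ``y = l_c`` and the open end of the downstream passage are *not* walls
    (they close the polygon for Voronoi clipping only).
    """

    variant: str
    b: float
    l_c: float
    w_e: float
    exit_depth: float
    wall_segments: np.ndarray
    walkable_polygon: Polygon = field(compare=False)

    def __post_init__(self) -> None:
        if self.variant not in ("corridor", "hopper"):
            raise GeometryError(f"unknown variant {self.variant!r}")
        if not self.walkable_polygon.is_simple:
            raise GeometryError("walkable polygon is self-intersecting")

    @property
    def exit_line(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """The flow-measurement segment at y = 0."""
        return ((-self.w_e / 2.0, 0.0), (self.w_e / 2.0, 0.0))

    @property
    def upstream_area(self) -> float:
        """Closed-form area of the part of the domain with y >= 0."""
        if self.variant == "corridor":
            return self.b * self.l_c
        half = (self.b - self.w_e) / 2.0
        return self.b * self.l_c - half**2

    def upstream_polygon(self, y_max: float | None = None) -> Polygon:
        """Walkable region with 0 <= y <= y_max (default: full corridor)."""
        if y_max is None:
            y_max = self.l_c
        clip = Polygon(
            [(-self.b, 0.0), (self.b, 0.0), (self.b, y_max), (-self.b, y_max)]
        )
        return self.walkable_polygon.intersection(clip)

    def distance_to_walls(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the nearest wall segment.

        Accepts a single (2,) point or an (n, 2) array; vectorised over both
        points and segments (the segment count is tiny).
        """
        return distance_to_segments(np.asarray(points, dtype=float), self.wall_segments)

    def config_dict(self) -> dict:
        return {
            "variant": self.variant,
            "b": self.b,
            "l_c": self.l_c,
            "w_e": self.w_e,
            "exit_depth": self.exit_depth,
        }


def distance_to_segments(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Distance from points (n,2) to the nearest of the given segments (m,2,2)."""
    pts = np.atleast_2d(points)
    a = segments[:, 0]  # (m, 2)
    ab = segments[:, 1] - a  # (m, 2)
    ab_len2 = np.maximum((ab**2).sum(axis=1), 1e-300)
    ap = pts[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip((ap * ab[None]).sum(axis=2) / ab_len2[None], 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2).min(axis=1)
    return d if points.ndim == 2 else float(d[0])


def _check_dims(b: float, l_c: float, w_e: float, exit_depth: float) -> None:
    for name, val in (("b", b), ("l_c", l_c), ("w_e", w_e), ("exit_depth", exit_depth)):
        if not val > 0:
            raise GeometryError(f"{name} must be positive, got {val}")
    if w_e > b:
        raise GeometryError(f"exit wider than corridor (w_e={w_e} > b={b})")


def build_corridor(
    b: float, l_c: float = 7.0, w_e: float = 0.5, exit_depth: float = 1.0
) -> Geometry:
    """Straight corridor with a centred door of width ``w_e`` at ``y = 0``."""
    _check_dims(b, l_c, w_e, exit_depth)
    hb, hw = b / 2.0, w_e / 2.0
    poly = orient(
        Polygon(
            [
                (-hw, -exit_depth),
                (hw, -exit_depth),
                (hw, 0.0),
                (hb, 0.0),
                (hb, l_c),
                (-hb, l_c),
                (-hb, 0.0),
                (-hw, 0.0),
            ]
        )
    )
    walls = np.array(
        [
            [(hb, 0.0), (hb, l_c)],  # right side wall
            [(-hb, 0.0), (-hb, l_c)],  # left side wall
            [(hw, 0.0), (hb, 0.0)],  # right bottom stub
            [(-hb, 0.0), (-hw, 0.0)],  # left bottom stub
            [(hw, -exit_depth), (hw, 0.0)],  # passage walls
            [(-hw, -exit_depth), (-hw, 0.0)],
        ]
    )
    return Geometry("corridor", b, l_c, w_e, exit_depth, walls, poly)


def build_hopper(
    b: float, l_c: float = 7.0, w_e: float = 0.5, exit_depth: float = 1.0
) -> Geometry:
    """Corridor whose bottom walls are 45° funnel segments from the door edges.

    The funnel walls run from (±w_e/2, 0) up to (±b/2, (b − w_e)/2), where
    they meet the vertical side walls.
    """
    _check_dims(b, l_c, w_e, exit_depth)
    hb, hw = b / 2.0, w_e / 2.0
    y_apex = (b - w_e) / 2.0
    if y_apex >= l_c:
        raise GeometryError("funnel walls would extend past the corridor end")
    poly = orient(
        Polygon(
            [
                (-hw, -exit_depth),
                (hw, -exit_depth),
                (hw, 0.0),
                (hb, y_apex),
                (hb, l_c),
                (-hb, l_c),
                (-hb, y_apex),
                (-hw, 0.0),
            ]
        )
    )
    walls = np.array(
        [
            [(hb, y_apex), (hb, l_c)],
            [(-hb, y_apex), (-hb, l_c)],
            [(hw, 0.0), (hb, y_apex)],  # 45° funnel walls
            [(-hb, y_apex), (-hw, 0.0)],
            [(hw, -exit_depth), (hw, 0.0)],
            [(-hw, -exit_depth), (-hw, 0.0)],
        ]
    )
    return Geometry("hopper", b, l_c, w_e, exit_depth, walls, poly)


def build_geometry(
    variant: str, b: float, l_c: float = 7.0, w_e: float = 0.5, exit_depth: float = 1.0
) -> Geometry:
    if variant == "corridor":
        return build_corridor(b, l_c, w_e, exit_depth)
    if variant == "hopper":
        return build_hopper(b, l_c, w_e, exit_depth)
    raise GeometryError(f"unknown variant {variant!r}")


def corridor_length(
    N: int, b: float, rho_i: float, l_min: float = 7.0
) -> float:
    """Corridor length giving initial density ``rho_i``, floored at ``l_min``.

    l_c = N / (b·rho_i) when that exceeds ``l_min`` (narrow corridors);
    otherwise the length is held constant at ``l_min``.
    """
    if N <= 0 or b <= 0 or rho_i <= 0 or l_min <= 0:
        raise GeometryError("corridor_length arguments must be positive")
    return max(N / (b * rho_i), l_min)


def export_walls_csv(geometry: Geometry, path) -> None:
    """Write wall segments as ``x1,y1,x2,y2`` rows (for plotting)."""
    rows = geometry.wall_segments.reshape(-1, 4)
    header = "x1,y1,x2,y2"
    np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt="%.6f")
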