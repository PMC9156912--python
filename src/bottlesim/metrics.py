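"""Measurement suite for bottleneck trajectories.

All observables operate on :class:`~bottlesim.dynamics.Trajectory` objects,
whether produced in-process or read back from a trajectory text file:

* Voronoi mean density in a measurement area (the standard estimator for
  pedestrian experiments: each agent contributes the inverse area of its
  Voronoi cell, clipped to the walkable domain),
* Gaussian-kernel density fields for lane visualisation,
* the interaction-angle distribution near the exit (angle between an agent's
  noiseless floor-field direction and the neighbour limiting its speed),
* waiting times T_w versus straight-line distance r to the exit centre and
  the power-law exponent α of T_w ∝ r^α,
* time gaps ΔT between consecutive exit crossings and N–t curves,
* the hexagonal-packing density bound used to calibrate the agent diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .dynamics import ModelParams, Trajectory, headway_spacing
from .floorfield import FloorField
from .geometry import Geometry, MeasurementArea

logger = logging.getLogger(__name__)

#: densest packing fraction of equal discs in the plane (hexagonal lattice)
HEX_PACKING_FRACTION = math.pi / math.sqrt(12.0)


def max_packing_density(r: float) -> float:
    """Maximal crowd density (m⁻²) for hexagonally packed discs of radius r."""
    if r <= 0:
        raise ValueError("disc radius must be positive")
    return HEX_PACKING_FRACTION / (math.pi * r**2)


# ---------------------------------------------------------------------------
# Voronoi density
# ---------------------------------------------------------------------------


def voronoi_cells(positions: np.ndarray, domain: Polygon) -> list[Polygon]:
    """Voronoi cells of the given points, clipped to the domain polygon.

    The tessellation is bounded by ghost points far outside the domain, so
    every real cell is finite before clipping; cells partition the domain.
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(pts)
    if n == 0:
        return []
    if n == 1:
        return [domain]
    minx, miny, maxx, maxy = domain.bounds
    span = max(maxx - minx, maxy - miny, 1.0)
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    ang = np.linspace(0.0, 2 * np.pi, 8, endpoint=False)
    ghosts = np.column_stack(
        [cx + 100.0 * span * np.cos(ang), cy + 100.0 * span * np.sin(ang)]
    )
    vor = Voronoi(np.vstack([pts, ghosts]))
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # qhull does not guarantee vertex order; cells are convex, sort by angle
        c = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
        cell = Polygon(verts[order])
        cells.append(cell.intersection(domain))
    return cells


def voronoi_mean_density(
    positions: np.ndarray,
    geometry: Geometry,
    area: MeasurementArea | Polygon,
) -> float:
    """Mean Voronoi density ρ = Σ_i |R_i ∩ A| / (A_i · |A|) in the area A.

    R_i is agent i's Voronoi cell clipped to the walkable polygon and
    A_i = |R_i| its area, so integrating the density over the whole domain
    recovers the agent count exactly. Zero agents give 0 (logged).
    """
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(pts) == 0:
        logger.debug("voronoi_mean_density called with zero agents")
        return 0.0
    domain = geometry.walkable_polygon
    from shapely import contains_xy

    if not contains_xy(domain.buffer(1e-9), pts[:, 0], pts[:, 1]).all():
        raise ValueError("agent position outside the walkable domain")
    a_poly = area.as_polygon() if isinstance(area, MeasurementArea) else area
    a_total = a_poly.area
    axmin, aymin, axmax, aymax = a_poly.bounds
    acc = 0.0
    for cell in voronoi_cells(pts, domain):
        if cell.is_empty:
            continue
        cxmin, cymin, cxmax, cymax = cell.bounds
        if cxmax < axmin or cxmin > axmax or cymax < aymin or cymin > aymax:
            continue
        overlap = cell.intersection(a_poly).area
        if overlap > 0.0:
            acc += overlap / cell.area
    return acc / a_total


def density_timeseries(
    traj: Trajectory,
    geometry: Geometry,
    area: MeasurementArea | Polygon | None = None,
    window: tuple[float, float] = (10.0, 15.0),
    sample_dt: float | None = None,
) -> pd.DataFrame:
    """Per-frame Voronoi density in the window; mean is the time average.

    ``sample_dt`` subsamples frames (defaults to every recorded frame).
    Returns a DataFrame with columns ``t`` and ``rho``; the interval mean is
    in ``df.attrs["mean"]``.
    """
    if area is None:
        area = MeasurementArea()
    t0, t1 = window
    frame_dt = traj.dt * traj.stride
    stride = 1 if sample_dt is None else max(1, int(round(sample_dt / frame_dt)))
    rows = []
    for f in range(0, len(traj.times), stride):
        t = traj.times[f]
        if t < t0 - 1e-9 or t > t1 + 1e-9:
            continue
        mask = traj.present_at(f)
        rho = voronoi_mean_density(traj.positions[f, mask], geometry, area)
        rows.append((t, rho))
    df = pd.DataFrame(rows, columns=["t", "rho"])
    df.attrs["mean"] = float(df["rho"].mean()) if len(df) else float("nan")
    return df


# ---------------------------------------------------------------------------
# Gaussian density field
# ---------------------------------------------------------------------------


@dataclass
class DensityField:
    """Frame-averaged Gaussian-kernel density on a regular grid (m⁻²)."""

    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray  # (ny, nx)
    kernel_width: float
    window: tuple[float, float]
    n_frames: int

    def integral(self) -> float:
        dx = self.xs[1] - self.xs[0]
        dy = self.ys[1] - self.ys[0]
        return float(self.values.sum() * dx * dy)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# density field a={self.kernel_width} window={self.window} "
                f"x0={self.xs[0]} y0={self.ys[0]} "
                f"dx={self.xs[1] - self.xs[0]} dy={self.ys[1] - self.ys[0]}\n"
            )
            np.savetxt(fh, self.values, fmt="%.6e")


def gaussian_density_field(
    traj: Trajectory,
    a: float = 0.2,
    spacing: float = 0.1,
    window: tuple[float, float] = (10.0, 30.0),
    bounds: tuple[float, float, float, float] | None = None,
) -> DensityField:
    """Superpose a unit-integral 2-D Gaussian per agent and average frames.

    The kernel is (1/(π a²))·exp(−|r − r_i|²/a²), a smooth stand-in for the
    point-particle delta so each agent contributes total mass 1.
    """
    if a <= 0:
        raise ValueError("kernel width must be positive")
    if spacing > a / 2 + 1e-12:
        raise ValueError("grid spacing must be <= a/2 to resolve the kernel")
    if bounds is None:
        g = traj.geometry_config
        bounds = (-g["b"] / 2.0, g["b"] / 2.0, 0.0, g["l_c"])
    x_min, x_max, y_min, y_max = bounds
    xs = np.arange(x_min, x_max + spacing / 2, spacing)
    ys = np.arange(y_min, y_max + spacing / 2, spacing)
    xx, yy = np.meshgrid(xs, ys)
    acc = np.zeros_like(xx)
    t0, t1 = window
    n_frames = 0
    norm = 1.0 / (math.pi * a * a)
    for f, t in enumerate(traj.times):
        if t < t0 - 1e-9 or t > t1 + 1e-9:
            continue
        n_frames += 1
        pts = traj.positions[f, traj.present_at(f)]
        for x, y in pts:
            acc += norm * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (a * a))
    if n_frames == 0:
        raise ValueError("no trajectory frames inside the averaging window")
    return DensityField(xs, ys, acc / n_frames, a, window, n_frames)


# ---------------------------------------------------------------------------
# Interaction angles
# ---------------------------------------------------------------------------


def interaction_angles(
    traj: Trajectory,
    floorfield: FloorField,
    params: ModelParams,
    radius: float = 1.0,
    t_min: float = 10.0,
) -> pd.DataFrame:
    """Angles between the noiseless desired directions of interacting agents.

    For every frame with t ≥ t_min and every not-yet-exited agent i within
    ``radius`` of the exit centre whose headway set is non-empty, emits the
    angle (degrees, [0, 180]) between the noiseless floor-field directions
    e_0(x_i) and e_0(x_j) of agent i and its limiting (argmin-spacing)
    neighbour j. Follower chains give small angles, side-by-side merging
    near 90°, and head-on deadlock configurations approach 180°. Headway
    sets are recomputed from positions with the noiseless e_0, so the
    metric applies equally to trajectory files.
    """
    rows: list[tuple[float, float]] = []
    for f, t in enumerate(traj.times):
        if t < t_min - 1e-9:
            continue
        present = traj.present_at(f)
        if present.sum() < 2:
            continue
        pos = traj.positions[f, present]
        up = traj.upstream_at(f)[present]
        e = np.empty_like(pos)
        if up.any():
            e[up] = floorfield.desired_direction(pos[up])
        e[~up] = (0.0, -1.0)
        s, jmin = headway_spacing(pos, e, params.l)
        r = np.hypot(pos[:, 0], pos[:, 1])
        sel = up & (r <= radius) & (jmin >= 0)
        for i in np.nonzero(sel)[0]:
            cosang = float(np.clip(e[i] @ e[jmin[i]], -1.0, 1.0))
            rows.append((t, math.degrees(math.acos(cosang))))
    return pd.DataFrame(rows, columns=["t", "angle"])


def angle_histogram(
    angles: np.ndarray | pd.Series, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram (probability per bin) of angles over [0°, 180°].

    Returns ``(bin_centers, probabilities)``; probabilities sum to 1.
    """
    if not float(180.0 / bin_width).is_integer():
        raise ValueError("bin width must divide 180")
    vals = np.asarray(angles, dtype=float)
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(vals, 0.0, 180.0 - 1e-9), bins=edges)
    total = counts.sum()
    probs = counts / total if total > 0 else counts.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, probs


def angle_modes(
    centers: np.ndarray, probs: np.ndarray, smooth_bins: int = 3
) -> list[tuple[float, float]]:
    """Peak locations of a binned angle distribution.

    Smooths with a ``smooth_bins``-wide moving average, then reports local
    maxima as (bin centre, smoothed mass), sorted by angle. Flat-topped
    plateaus count once, at their first bin.
    """
    kernel = np.ones(smooth_bins) / smooth_bins
    sm = np.convolve(probs, kernel, mode="same")
    peaks = []
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] > left and sm[i] >= right and sm[i] > 0:
            peaks.append((float(centers[i]), float(sm[i])))
    return peaks


# ---------------------------------------------------------------------------
# Waiting times and power-law fit
# ---------------------------------------------------------------------------


def waiting_time_samples(
    traj: Trajectory,
    window: tuple[float, float] = (10.0, 20.0),
    sample_interval: float = 0.5,
) -> pd.DataFrame:
    """(r, T_w) samples: distance to the exit centre vs remaining time.

    At each sample time t and for every agent still upstream at t that
    eventually exits, r = |x_i(t)| is the straight-line distance from the
    exit centre and T_w = exit_time − t. Agents that never exit are skipped
    (count logged).
    """
    rows = []
    skipped = 0
    t0, t1 = window
    for t in np.arange(t0, t1 + 1e-9, sample_interval):
        f = traj.frame_at(t)
        up = traj.upstream_at(f)
        for i in np.nonzero(up)[0]:
            te = traj.exit_times[i]
            if np.isnan(te):
                skipped += 1
                continue
            if te <= t:
                continue
            r = float(np.hypot(*traj.positions[f, i]))
            rows.append((t, i, r, te - t))
    if skipped:
        logger.debug("skipped %d samples from agents that never exit", skipped)
    return pd.DataFrame(rows, columns=["t", "agent", "r", "T_w"])


@dataclass
class PowerLawFit:
    """Least-squares fit of log T_w against log r."""

    alpha: float
    prefactor: float
    r_min: float
    r_max: float
    n_samples: int
    alpha_stderr: float

    def predict(self, r: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(r) ** self.alpha


def fit_power_law(
    r: np.ndarray,
    t_w: np.ndarray,
    r_min: float = 0.3,
    r_max: float = 1.5,
    min_samples: int = 10,
) -> PowerLawFit:
    """Fit T_w ∝ r^α by OLS on log–log data restricted to [r_min, r_max]."""
    r = np.asarray(r, dtype=float)
    t_w = np.asarray(t_w, dtype=float)
    mask = (r >= r_min) & (r <= r_max) & (t_w > 0) & (r > 0)
    n = int(mask.sum())
    if n < min_samples:
        raise ValueError(f"only {n} samples inside [{r_min}, {r_max}] (need {min_samples})")
    x = np.log(r[mask])
    y = np.log(t_w[mask])
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    return PowerLawFit(
        alpha=float(slope),
        prefactor=float(np.exp(intercept)),
        r_min=r_min,
        r_max=r_max,
        n_samples=n,
        alpha_stderr=float(np.sqrt(cov[0, 0])),
    )


# ---------------------------------------------------------------------------
# Exit crossings
# ---------------------------------------------------------------------------


@dataclass
class TimeGapStats:
    """Mean time gap between consecutive exit crossings (head/tail trimmed)."""

    mean_gap: float
    gaps: np.ndarray
    excluded_head: int
    excluded_tail: int
    n_crossings: int

    @property
    def empty(self) -> bool:
        return len(self.gaps) == 0


def exit_crossings_and_gaps(
    exit_times: np.ndarray, exclude: int = 10
) -> TimeGapStats:
    """Gaps ΔT between consecutive y=0 crossings, trimming first/last agents.

    The first and last ``exclude`` crossings of the run are dropped before
    differencing (start-up and tail transients). Fewer than 2·exclude + 2
    crossings give an empty (flagged) result.
    """
    times = np.sort(np.asarray(exit_times, dtype=float))
    times = times[np.isfinite(times)]
    n = len(times)
    if n < 2 * exclude + 2:
        return TimeGapStats(float("nan"), np.array([]), exclude, exclude, n)
    core = times[exclude : n - exclude] if exclude > 0 else times
    gaps = np.diff(core)
    return TimeGapStats(float(gaps.mean()), gaps, exclude, exclude, n)


def n_t_curve(exit_times: np.ndarray) -> pd.DataFrame:
    """Cumulative number of exited agents versus time."""
    times = np.sort(np.asarray(exit_times, dtype=float))
    times = times[np.isfinite(times)]
    return pd.DataFrame({"t": times, "n_exited": np.arange(1, len(times) + 1)})
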