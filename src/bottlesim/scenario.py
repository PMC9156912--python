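"""Scenario construction and replicate orchestration.

A scenario fixes the geometry variant, corridor width b, agent count N and
the model parameters, and randomises the initial condition per replicate:
the initial density ρ_i is drawn from U(2.0, 3.0) m⁻², the corridor length
is l_c = max(N/(b·ρ_i), 7 m) so that N agents evenly spread over the
corridor realise that density, and agents are placed uniformly at random
with hard-core rejection (pairwise distance ≥ l, wall clearance ≥ l/2).

Floor fields depend only on the geometry, not on the initial condition, and
solving the Eikonal equation is the expensive part of a run; fields are
cached per (variant, b, w_e, grid) with the corridor length rounded *up* to
the next metre. A field computed for a longer corridor is exact for any
shorter one because cost-optimal paths never run away from the exit, so the
cache also covers the per-replicate variation of l_c in narrow corridors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import dynamics, metrics
from .dynamics import ModelParams, Trajectory
from .floorfield import FloorField, compute_floor_field
from .geometry import Geometry, MeasurementArea, build_geometry, corridor_length

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation experiment cell."""

    variant: str = "corridor"
    b: float = 5.6  # corridor width, m
    N: int = 55  # number of agents
    T: float = 1.3  # slope factor (motivation), s
    v0: float = 1.34  # desired speed, m/s
    l: float = 0.35  # agent diameter, m
    sigma: float = 0.7  # direction-noise variance
    sigma_is_variance: bool = True
    dt: float = 0.05  # time step, s
    dh: float = 0.01  # floor-field resolution, m
    d_w: float = 0.25  # wall-avoidance distance, m
    g: float = 3.0  # wall slowness gain
    w_e: float = 0.5  # exit (door) width, m
    exit_depth: float = 1.0  # downstream passage length, m
    rho_i_range: tuple[float, float] = (2.0, 3.0)  # initial density draw, m^-2
    l_c_min: float = 7.0  # corridor length floor, m
    replicates: int = 500
    base_seed: int = 0
    windows: tuple[tuple[float, float], ...] = ((5.0, 10.0), (10.0, 15.0))
    horizon: float = 60.0  # s
    stride: int = 1  # frame recording stride
    density_sample_dt: float = 0.25  # s between Voronoi density evaluations

    def model_params(self) -> ModelParams:
        return ModelParams(
            v0=self.v0,
            l=self.l,
            T=self.T,
            sigma=self.sigma,
            dt=self.dt,
            sigma_is_variance=self.sigma_is_variance,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rho_i_range"] = list(self.rho_i_range)
        d["windows"] = [list(w) for w in self.windows]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        """Build from a config mapping; Table-style short names accepted."""
        aliases = {"dw": "d_w", "we": "w_e", "n": "N"}
        kwargs: dict = {}
        for key, val in raw.items():
            key = aliases.get(key, key)
            kwargs[key] = val
        if "rho_i_range" in kwargs:
            kwargs["rho_i_range"] = tuple(kwargs["rho_i_range"])
        if "windows" in kwargs:
            kwargs["windows"] = tuple(tuple(w) for w in kwargs["windows"])
        return cls(**kwargs)


def sample_initial_density(
    rng: np.random.Generator, rho_range: tuple[float, float] = (2.0, 3.0)
) -> float:
    """Initial corridor density ρ_i ~ U(2.0, 3.0) m⁻² (range configurable)."""
    return float(rng.uniform(*rho_range))


class PlacementError(RuntimeError):
    pass


def place_agents(
    geometry: Geometry,
    N: int,
    rng: np.random.Generator,
    l: float = 0.35,
    max_tries_per_agent: int = 2000,
) -> np.ndarray:
    """N hard-core positions uniform over the upstream corridor.

    Rejection sampling: candidates are uniform over the corridor rectangle
    and accepted when inside the walkable polygon with wall clearance ≥ l/2
    and pairwise centre distance ≥ l to all accepted agents.
    """
    area = geometry.upstream_area
    if N * math.pi * (l / 2.0) ** 2 >= 0.5 * area:
        raise PlacementError(
            f"placement density infeasible: N·π(l/2)² = "
            f"{N * math.pi * (l / 2) ** 2:.2f} m² ≥ half the corridor area "
            f"{0.5 * area:.2f} m²"
        )
    from shapely import contains_xy

    hb = geometry.b / 2.0
    positions: list[np.ndarray] = []
    placed = np.empty((0, 2))
    for i in range(N):
        for _ in range(max_tries_per_agent):
            cand = np.array(
                [
                    rng.uniform(-hb + l / 2.0, hb - l / 2.0),
                    rng.uniform(l / 2.0, geometry.l_c - l / 2.0),
                ]
            )
            if not contains_xy(geometry.walkable_polygon, cand[0], cand[1]):
                continue
            if geometry.distance_to_walls(cand) < l / 2.0:
                continue
            if len(placed) and np.hypot(*(placed - cand).T).min() < l:
                continue
            positions.append(cand)
            placed = np.asarray(positions)
            break
        else:
            raise PlacementError(
                f"could not place agent {i + 1}/{N} after "
                f"{max_tries_per_agent} tries (corridor too crowded)"
            )
    return placed


class FloorFieldCache:
    """Memoises solved floor fields across replicates.

    The corridor length enters the key rounded up to the next metre; the
    cached field is computed at that length and is exact for any shorter
    corridor (see module docstring).
    """

    def __init__(self) -> None:
        self._cache: dict[tuple, FloorField] = {}

    def get(self, config: ScenarioConfig, l_c: float) -> FloorField:
        lc_key = math.ceil(l_c - 1e-9)
        key = (
            config.variant,
            round(config.b, 9),
            round(config.w_e, 9),
            round(config.exit_depth, 9),
            round(config.dh, 9),
            round(config.d_w, 9),
            round(config.g, 9),
            lc_key,
        )
        if key not in self._cache:
            geo = build_geometry(
                config.variant, config.b, float(lc_key), config.w_e, config.exit_depth
            )
            self._cache[key] = compute_floor_field(geo, config.dh, config.d_w, config.g)
        return self._cache[key]


@dataclass
class RunResult:
    """One replicate: its trajectory plus the sampled initial condition."""

    seed: int
    rho_i: float
    l_c: float
    geometry: Geometry
    floorfield: FloorField
    trajectory: Trajectory


def run_single(
    config: ScenarioConfig, seed: int, cache: FloorFieldCache | None = None
) -> RunResult:
    """One replicate: draw ρ_i, derive l_c, place agents, simulate."""
    rng = np.random.default_rng(seed)
    rho_i = sample_initial_density(rng, config.rho_i_range)
    l_c = corridor_length(config.N, config.b, rho_i, config.l_c_min)
    geometry = build_geometry(
        config.variant, config.b, l_c, config.w_e, config.exit_depth
    )
    if cache is None:
        ff = compute_floor_field(geometry, config.dh, config.d_w, config.g)
    else:
        ff = cache.get(config, l_c)
    positions = place_agents(geometry, config.N, rng, config.l)
    traj = dynamics.run(
        geometry,
        ff,
        config.model_params(),
        positions,
        seed=seed,
        rng=rng,
        horizon=config.horizon,
        stride=config.stride,
    )
    traj.meta.update(
        {"dh": config.dh, "d_w": config.d_w, "g": config.g, "rho_i": rho_i}
    )
    return RunResult(seed, rho_i, l_c, geometry, ff, traj)


def iter_runs(config: ScenarioConfig, n_runs: int, base_seed: int | None = None):
    """Yield RunResults for seeds base_seed, base_seed+1, …"""
    if base_seed is None:
        base_seed = config.base_seed
    cache = FloorFieldCache()
    for k in range(n_runs):
        yield run_single(config, base_seed + k, cache)


def run_metrics_row(config: ScenarioConfig, result: RunResult) -> dict:
    """Standard per-run measurement row (densities, α, ΔT, evacuation)."""
    traj = result.trajectory
    area = MeasurementArea()
    row: dict = {
        "seed": result.seed,
        "b": config.b,
        "T": config.T,
        "N": config.N,
        "variant": config.variant,
        "rho_i": result.rho_i,
        "l_c": result.l_c,
    }
    for w in config.windows:
        series = metrics.density_timeseries(
            traj, result.geometry, area, window=w, sample_dt=config.density_sample_dt
        )
        row[f"rho_{w[0]:g}_{w[1]:g}"] = series.attrs["mean"]
    wt = metrics.waiting_time_samples(traj)
    try:
        fit = metrics.fit_power_law(wt["r"], wt["T_w"])
        row["alpha"] = fit.alpha
        row["alpha_n"] = fit.n_samples
    except ValueError:
        row["alpha"] = float("nan")
        row["alpha_n"] = 0
    gaps = metrics.exit_crossings_and_gaps(traj.exit_times)
    row["mean_dT"] = gaps.mean_gap
    row["n_exited"] = int(np.isfinite(traj.exit_times).sum())
    finite = traj.exit_times[np.isfinite(traj.exit_times)]
    row["last_exit"] = float(finite.max()) if len(finite) else float("nan")
    return row


def run_replicates(
    config: ScenarioConfig, n_runs: int | None = None, base_seed: int | None = None
) -> pd.DataFrame:
    """Replicate table: one measurement row per seed.

    Individual replicate failures are recorded (``error`` column) rather
    than aborting the sweep.
    """
    if n_runs is None:
        n_runs = config.replicates
    if base_seed is None:
        base_seed = config.base_seed
    rows = []
    cache = FloorFieldCache()
    for k in range(n_runs):
        seed = base_seed + k
        try:
            result = run_single(config, seed, cache)
            rows.append(run_metrics_row(config, result))
        except Exception as exc:  # noqa: BLE001 - per-run isolation is the point
            logger.error("replicate seed=%d failed: %s", seed, exc)
            rows.append({"seed": seed, "b": config.b, "T": config.T, "error": str(exc)})
    return pd.DataFrame(rows)


def summarize_sweep(per_run: pd.DataFrame) -> pd.DataFrame:
    """Per (b, T): mean and 2.5–97.5 percentile band of each density column.

    Mirrors how sweep results are reported: the mean over replicates with a
    95% range across runs.
    """
    dens_cols = [c for c in per_run.columns if c.startswith("rho_") and c != "rho_i"]
    out = []
    for (b, T), grp in per_run.groupby(["b", "T"]):
        row: dict = {"b": b, "T": T, "n_runs": len(grp)}
        for col in dens_cols:
            vals = grp[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            row[f"{col}_mean"] = float(vals.mean())
            row[f"{col}_lo"] = float(np.percentile(vals, 2.5))
            row[f"{col}_hi"] = float(np.percentile(vals, 97.5))
        if "alpha" in grp:
            vals = grp["alpha"].dropna().to_numpy()
            if len(vals):
                row["alpha_mean"] = float(vals.mean())
        if "mean_dT" in grp:
            vals = grp["mean_dT"].dropna().to_numpy()
            if len(vals):
                row["mean_dT_mean"] = float(vals.mean())
        out.append(row)
    return pd.DataFrame(out).sort_values(["T", "b"]).reset_index(drop=True)


def waiting_time_exponent(
    config: ScenarioConfig, n_runs: int, base_seed: int | None = None
) -> dict:
    """Waiting-time power-law exponent α for one scenario cell.

    Fits T_w ∝ r^α per run on the (r, T_w) samples taken every 0.5 s over
    t ∈ [10, 20] s (r restricted to [0.3, 1.5] m) and reports the mean of
    the per-run exponents, the convention used for exponent-versus-width
    and exponent-versus-N curves. A per-run slope is only meaningful when
    its samples cover a real range of distances: runs with fewer than 10
    in-range samples or whose in-range r values span less than a factor of
    2 are skipped (logged). The pooled-sample fit is reported alongside.
    """
    alphas = []
    rs, tws = [], []
    for result in iter_runs(config, n_runs, base_seed):
        wt = metrics.waiting_time_samples(result.trajectory)
        rs.append(wt["r"].to_numpy())
        tws.append(wt["T_w"].to_numpy())
        try:
            fit = metrics.fit_power_law(wt["r"], wt["T_w"])
            in_range = wt["r"][(wt["r"] >= fit.r_min) & (wt["r"] <= fit.r_max)]
            if in_range.max() < 2.0 * in_range.min():
                logger.info(
                    "seed %d: waiting-time samples span too little of the "
                    "fit range for a meaningful slope",
                    result.seed,
                )
                continue
            alphas.append(fit.alpha)
        except ValueError:
            logger.info("seed %d: too few waiting-time samples", result.seed)
    pooled = metrics.fit_power_law(np.concatenate(rs), np.concatenate(tws))
    return {
        "alpha": float(np.mean(alphas)),
        "alpha_sd": float(np.std(alphas)),
        "n_fits": len(alphas),
        "pooled_alpha": pooled.alpha,
        "n_samples": pooled.n_samples,
    }


def with_overrides(config: ScenarioConfig, **kwargs) -> ScenarioConfig:
    """Convenience: a copy of the config with fields replaced."""
    return replace(config, **kwargs)
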