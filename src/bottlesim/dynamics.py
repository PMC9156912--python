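"""Collision-free speed model dynamics.

Each agent i is a hard disc of diameter l moving with velocity
``v_i = V(s_i) · e_i`` where ``s_i`` is the distance to the nearest agent in
its headway (the forward half-plane of ``e_i`` within a lateral band of one
body diameter) and

    V(s) = min{ v0, max{0, (s − l)/T} }.

The slope factor T plays the role of motivation: small T means gaps are
closed aggressively (high motivation), large T means speed is reduced early
(low motivation). The desired direction comes from the floor field and is
perturbed every step by white noise, ``e_i = (e_0 + ζ)/Z`` with both
components of ζ normal with zero mean and variance σ; the noise both models
imperfect steering and resolves deadlocks that the deterministic model admits.

Updates are synchronous. A guard pass freezes (speed 0 for this step) every
agent whose candidate position would overlap another agent or leave the
walkable domain, iterating until the configuration is valid; this mirrors
the model's rule that velocity drops to zero on contact and guarantees the
hard-core exclusion invariant exactly. Walls otherwise act only through the
floor field's slowness ramp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely import contains_xy

from ._kernels import contact_gamma_kernel, headway_spacing_kernel
from .floorfield import FloorField
from .geometry import Geometry

logger = logging.getLogger(__name__)

#: spacing sentinel for agents with an empty headway set
NO_NEIGHBOR = np.inf

#: numerical tolerance on the hard-core exclusion
EPS = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Per-run model constants (SI units)."""

    v0: float = 1.34  # desired speed, m/s
    l: float = 0.35  # agent diameter (hard-core exclusion), m
    T: float = 1.3  # slope factor (motivation), s
    sigma: float = 0.7  # direction noise variance (dimensionless)
    dt: float = 0.05  # time step, s
    sigma_is_variance: bool = True  # if False, sigma is a standard deviation

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.l <= 0:
            raise ValueError("v0 and l must be positive")
        if self.T < 0 or self.sigma < 0:
            raise ValueError("T and sigma must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T > 0:
            if self.dt > self.T / 2 + 1e-12:
                raise ValueError(
                    f"dt={self.dt} exceeds the overlap-safety bound T/2={self.T / 2}"
                )
        elif self.dt > 0.05 + 1e-12:
            raise ValueError("dt must be <= 0.05 s when T = 0")

    @property
    def noise_std(self) -> float:
        return float(np.sqrt(self.sigma)) if self.sigma_is_variance else self.sigma


def speed(s: np.ndarray | float, params: ModelParams) -> np.ndarray | float:
    """Speed function V(s) = min{v0, max{0, (s − l)/T}}.

    The sentinel spacing (empty headway) gives v0. In the limit T → 0 the
    model reduces to simple volume exclusion: v0 whenever s > l, else 0.
    """
    s_arr = np.asarray(s, dtype=float)
    if params.T > 0:
        v = np.minimum(params.v0, np.maximum(0.0, (s_arr - params.l) / params.T))
    else:
        v = np.where(s_arr > params.l, params.v0, 0.0)
    v = np.where(np.isinf(s_arr), params.v0, v)
    return float(v) if np.isscalar(s) or np.asarray(s).ndim == 0 else v


def headway_spacing(
    pos: np.ndarray, e: np.ndarray, l: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimal spacing s_i and argmin neighbour index for every agent.

    An agent j is in i's headway set J_i when j lies in the forward
    half-plane of e_i (the unit vector from i to j has non-negative dot
    product with e_i) and the perpendicular distance of j's centre from i's
    movement line is < l. Returns ``(s, jmin)`` with the sentinel and −1
    where J_i is empty. Ties take the lowest agent index.
    """
    n = len(pos)
    if n < 2:
        return np.full(n, NO_NEIGHBOR), np.full(n, -1, dtype=np.int64)
    return headway_spacing_kernel(
        np.ascontiguousarray(pos, dtype=float),
        np.ascontiguousarray(e, dtype=float),
        l,
    )


def neighbor_set(i: int, pos: np.ndarray, e_i: np.ndarray, l: float) -> list[int]:
    """Headway set J_i of a single agent (convenience / inspection form)."""
    diff = pos - pos[i]
    dist = np.hypot(diff[:, 0], diff[:, 1])
    longi = diff @ e_i
    lat = np.abs(e_i[0] * diff[:, 1] - e_i[1] * diff[:, 0])
    mask = (longi >= 0.0) & (lat < l)
    mask[i] = False
    return list(np.nonzero(mask)[0])


def minimal_spacing(
    i: int, pos: np.ndarray, e_i: np.ndarray, l: float
) -> tuple[float, int]:
    """Minimal centre distance over J_i and the argmin id (−1 if empty)."""
    members = neighbor_set(i, pos, e_i, l)
    if not members:
        return NO_NEIGHBOR, -1
    d = np.hypot(*(pos[members] - pos[i]).T)
    k = int(np.argmin(d))  # members are id-sorted; first minimum = lowest id
    return float(d[k]), members[k]


def perturb_direction(
    e0: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Noisy movement direction (e_0 + ζ)/Z, ζ ~ N(0, σ) per component.

    Vectorised over rows of ``e0``; degenerate draws with |e_0 + ζ| ≈ 0 are
    redrawn (logged).
    """
    e0 = np.atleast_2d(e0)
    std = params.noise_std
    if std == 0.0:
        out = e0.copy()
    else:
        out = e0 + rng.normal(0.0, std, size=e0.shape)
    norm = np.hypot(out[:, 0], out[:, 1])
    while (bad := norm < 1e-12).any():
        logger.debug("redrawing %d degenerate direction draws", int(bad.sum()))
        out[bad] = e0[bad] + rng.normal(0.0, std, size=(int(bad.sum()), 2))
        norm = np.hypot(out[:, 0], out[:, 1])
    return out / norm[:, None]


@dataclass
class SimulationState:
    """Mutable state of one run; agent arrays are indexed by agent id."""

    t: float
    pos: np.ndarray  # (N, 2), last known position (frozen after removal)
    e: np.ndarray  # (N, 2) movement direction of the last step
    spd: np.ndarray  # (N,) speed of the last step
    present: np.ndarray  # (N,) bool, still inside the simulated domain
    upstream: np.ndarray  # (N,) bool, has not yet crossed y = 0
    exit_times: np.ndarray  # (N,) float, NaN until the agent crosses y = 0
    exit_order: list[int] = field(default_factory=list)

    @property
    def n_agents(self) -> int:
        return len(self.pos)

    @property
    def n_not_exited(self) -> int:
        return int(self.upstream.sum())


def new_state(positions: np.ndarray) -> SimulationState:
    n = len(positions)
    return SimulationState(
        t=0.0,
        pos=np.array(positions, dtype=float),
        e=np.tile([0.0, -1.0], (n, 1)),
        spd=np.zeros(n),
        present=np.ones(n, dtype=bool),
        upstream=np.ones(n, dtype=bool),
        exit_times=np.full(n, np.nan),
    )


def step(
    state: SimulationState,
    geometry: Geometry,
    floorfield: FloorField,
    params: ModelParams,
    rng: np.random.Generator,
) -> SimulationState:
    """Advance all present agents by one synchronous time step."""
    idx = np.nonzero(state.present)[0]
    if len(idx) == 0:
        state.t += params.dt
        return state
    pos = state.pos[idx]
    up = state.upstream[idx]

    e = np.empty_like(pos)
    if up.any():
        e0 = floorfield.desired_direction(pos[up])
        e[up] = perturb_direction(e0, params, rng)
    # agents already through the door walk straight down the passage
    e[~up] = (0.0, -1.0)

    s, _ = headway_spacing(pos, e, params.l)
    v = speed(s, params)
    n = len(idx)
    disp = (v * params.dt)[:, None] * e
    cand = pos + disp

    # Collision guard: an agent that would hit a neighbour during the step
    # moves along e_i only until contact, where its velocity drops to zero.
    # Agents are resolved in ascending id order against the finalised
    # positions of already-resolved neighbours and the held positions of the
    # rest, which keeps every pairwise distance >= l by construction.
    gamma = np.ones(n)
    moving = v > 0
    # candidates leaving the walkable domain are frozen outright: walls act
    # through the floor-field slowness, the guard only prevents tunnelling
    gamma[moving & ~contains_xy(geometry.walkable_polygon, cand[:, 0], cand[:, 1])] = 0.0
    if n > 1:
        gamma = contact_gamma_kernel(
            np.ascontiguousarray(pos),
            np.ascontiguousarray(disp),
            gamma,
            params.l + EPS,
        )
    new_pos = pos + gamma[:, None] * disp

    # no cutting the door corner: a centre path crossing y = 0 outside the
    # exit opening would tunnel through the lower wall tip
    sign_change = (pos[:, 1] > 0.0) & (new_pos[:, 1] <= 0.0)
    if sign_change.any():
        frac = pos[sign_change, 1] / (pos[sign_change, 1] - new_pos[sign_change, 1])
        x_cross = pos[sign_change, 0] + frac * (
            new_pos[sign_change, 0] - pos[sign_change, 0]
        )
        bad = np.abs(x_cross) > geometry.w_e / 2.0
        if bad.any():
            which = np.nonzero(sign_change)[0][bad]
            gamma[which] = 0.0
            new_pos[which] = pos[which]
    v = gamma * v

    # Door crossings: the crossing time at y = 0 is linearly interpolated
    # within the step; the agent then walks on down the passage (still a
    # hard disc, so the doorway stays physically blocked just after the
    # crossing) and is removed at the end of the passage.
    crossed = up & (pos[:, 1] >= 0.0) & (new_pos[:, 1] < 0.0)
    if crossed.any():
        frac = pos[crossed, 1] / (pos[crossed, 1] - new_pos[crossed, 1])
        times = state.t + frac * params.dt
        for agent, tc in sorted(zip(idx[crossed], times), key=lambda p: p[1]):
            state.exit_times[agent] = tc
            state.exit_order.append(int(agent))
        state.upstream[idx[crossed]] = False

    state.pos[idx] = new_pos
    state.e[idx] = e
    state.spd[idx] = v
    # remove agents once they are deep enough into the downstream passage
    gone = new_pos[:, 1] < -(geometry.exit_depth - params.l / 2.0)
    if gone.any():
        state.present[idx[gone]] = False
    state.t += params.dt
    return state


@dataclass
class Trajectory:
    """Frame-indexed positions of one run plus its exit records.

    ``positions[f, i]`` is agent i's centre at ``times[f]``; NaN once the
    agent has left the simulated domain. ``exit_times[i]`` is the
    interpolated time agent i crossed y = 0 (NaN if it never did).
    """

    dt: float
    stride: int
    times: np.ndarray  # (F,)
    positions: np.ndarray  # (F, N, 2)
    exit_times: np.ndarray  # (N,)
    params: ModelParams
    geometry_config: dict
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def present_at(self, frame: int) -> np.ndarray:
        return ~np.isnan(self.positions[frame, :, 0])

    def upstream_at(self, frame: int) -> np.ndarray:
        """Agents that have not yet crossed the exit line at this frame."""
        t = self.times[frame]
        return self.present_at(frame) & ~(self.exit_times <= t)

    def frame_at(self, t: float) -> int:
        return int(np.clip(np.round(t / (self.dt * self.stride)), 0, len(self.times) - 1))


def run(
    geometry: Geometry,
    floorfield: FloorField,
    params: ModelParams,
    positions: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    horizon: float = 60.0,
    stride: int = 1,
) -> Trajectory:
    """Simulate until every agent has left or the horizon is reached.

    Frames are recorded every ``stride`` steps (frame 0 is the initial
    condition). A warning is logged if agents remain at the horizon.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    state = new_state(positions)
    # starting cells must be reachable
    floorfield.desired_direction(state.pos)
    n_steps = int(np.round(horizon / params.dt))
    frames = [state.pos.copy()]
    times = [0.0]
    for k in range(1, n_steps + 1):
        step(state, geometry, floorfield, params, rng)
        if k % stride == 0:
            p = state.pos.copy()
            p[~state.present] = np.nan
            frames.append(p)
            times.append(state.t)
        if not state.present.any():
            break
    if state.upstream.any():
        logger.warning(
            "horizon %.1f s reached with %d agents still upstream",
            horizon,
            state.n_not_exited,
        )
    return Trajectory(
        dt=params.dt,
        stride=stride,
        times=np.asarray(times),
        positions=np.asarray(frames),
        exit_times=state.exit_times.copy(),
        params=params,
        geometry_config=geometry.config_dict(),
        seed=seed,
    )
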