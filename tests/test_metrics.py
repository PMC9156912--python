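import numpy as np
import pytest
from shapely.geometry import Polygon

import bottlesim as bs
from bottlesim.dynamics import ModelParams, Trajectory
from bottlesim.geometry import MeasurementArea
from bottlesim.metrics import (
    HEX_PACKING_FRACTION,
    angle_histogram,
    angle_modes,
    exit_crossings_and_gaps,
    fit_power_law,
    gaussian_density_field,
    max_packing_density,
    n_t_curve,
    voronoi_mean_density,
    waiting_time_samples,
)


def make_traj(frames, dt=0.5, exit_times=None, geometry_config=None, T=1.3):
    """Small hand-built trajectory helper."""
    positions = np.asarray(frames, dtype=float)
    n = positions.shape[1]
    return Trajectory(
        dt=dt,
        stride=1,
        times=np.arange(positions.shape[0]) * dt,
        positions=positions,
        exit_times=np.full(n, np.nan) if exit_times is None else np.asarray(exit_times),
        params=ModelParams(T=T),
        geometry_config=geometry_config or {"variant": "corridor", "b": 2.0, "l_c": 7.0},
    )


# -- packing bound ----------------------------------------------------------


def test_hex_packing_constants():
    assert HEX_PACKING_FRACTION == pytest.approx(0.9069, abs=5e-5)
    assert max_packing_density(0.175) == pytest.approx(9.43, abs=5e-3)
    assert max_packing_density(0.5) == pytest.approx(
        HEX_PACKING_FRACTION / (np.pi * 0.25)
    )
    # identity ρ_max(r)·πr²/η = 1
    for r in (0.1, 0.175, 1.7):
        assert max_packing_density(r) * np.pi * r**2 / HEX_PACKING_FRACTION == (
            pytest.approx(1.0)
        )


def test_hex_packing_against_lattice_count_oracle():
    """Brute force: count hexagonal lattice discs of radius r in a big box."""
    r = 0.5
    a = 2 * r  # lattice constant
    L = 60.0
    xs = np.arange(-L / 2, L / 2, a)
    rows = int(L / (a * np.sqrt(3) / 2))
    count = 0
    for k in range(rows):
        y = k * a * np.sqrt(3) / 2 - L / 2
        offset = (k % 2) * a / 2
        count += np.sum((xs + offset >= -L / 2) & (xs + offset < L / 2) & (abs(y) <= L / 2))
    density = count / L**2
    assert max_packing_density(r) == pytest.approx(density, rel=0.02)


# -- Voronoi density --------------------------------------------------------


def test_single_agent_fills_closed_domain():
    geo = bs.build_corridor(1.0, 1.0, 0.5, 0.2)
    box = Polygon([(-0.5, 0), (0.5, 0), (0.5, 1), (-0.5, 1)])  # upstream square
    rho = voronoi_mean_density(np.array([[0.2, 0.7]]), geo, box)
    # one agent, cell = whole domain (area 1.1 with the passage): the box
    # holds |box|/|domain| of the agent's unit mass
    assert rho == pytest.approx(1.0 / geo.walkable_polygon.area, rel=1e-6)


def test_lattice_density_against_grid_sampling_oracle():
    """5×5 lattice, spacing 0.5 m: central cell density is 4 agents/m²."""
    pts = np.array(
        [[0.25 + 0.5 * i, 0.25 + 0.5 * j] for i in range(5) for j in range(5)]
    )
    box = Polygon([(0, 0), (2.5, 0), (2.5, 2.5), (0, 2.5)])
    area = Polygon([(1.0, 1.0), (1.5, 1.0), (1.5, 1.5), (1.0, 1.5)])

    # oracle: dense grid sampling of p(x) = 1/A_cell(x)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    gx, gy = np.meshgrid(np.linspace(1.0, 1.5, 101), np.linspace(1.0, 1.5, 101))
    _, owner = tree.query(np.column_stack([gx.ravel(), gy.ravel()]))
    cell_area = 0.25  # interior cells are 0.5×0.5 squares
    p = 1.0 / cell_area
    oracle = p * 1.0  # all sampled points belong to interior cells
    del owner

    from bottlesim.metrics import voronoi_cells

    cells = voronoi_cells(pts, box)
    acc = sum(
        c.intersection(area).area / c.area for c in cells if c.intersects(area)
    )
    rho = acc / area.area
    assert rho == pytest.approx(4.0, rel=1e-9)
    assert rho == pytest.approx(oracle, rel=1e-9)


def test_whole_domain_density_is_count_over_area(corridor_56):
    rng = np.random.default_rng(0)
    pts = bs.place_agents(corridor_56, 30, rng)
    rho = voronoi_mean_density(pts, corridor_56, corridor_56.walkable_polygon)
    assert rho == pytest.approx(30 / corridor_56.walkable_polygon.area, rel=1e-9)


def test_density_bounded_by_hex_packing(short_noisy_run, corridor_56):
    area = MeasurementArea()
    df = bs.density_timeseries(
        short_noisy_run, corridor_56, area, window=(0.0, 10.0), sample_dt=1.0
    )
    bound = max_packing_density(0.35 / 2)
    assert (df["rho"] <= bound * 1.02).all()


def test_density_timeseries_static_agents(corridor_56):
    pos = np.array([[0.0, 0.9], [0.3, 1.2], [-0.4, 0.7], [1.5, 3.0]])
    frames = np.repeat(pos[None], 11, axis=0)
    traj = make_traj(frames, dt=0.5, geometry_config={"variant": "corridor", "b": 5.6, "l_c": 7.0})
    df = bs.density_timeseries(traj, corridor_56, MeasurementArea(), window=(0, 5))
    assert df["rho"].std() == pytest.approx(0.0, abs=1e-12)
    assert df.attrs["mean"] == pytest.approx(df["rho"].iloc[0])
    # naive averaging oracle
    assert df.attrs["mean"] == pytest.approx(df["rho"].mean())


def test_density_zero_agents_and_sparse_tail(corridor_56):
    # no agents at all: density 0
    assert voronoi_mean_density(np.empty((0, 2)), corridor_56, MeasurementArea()) == 0.0
    # agents far upstream: their sprawling cells dilute the measured density
    pos = np.array([[2.0, 6.0], [1.0, 5.0], [-2.0, 6.5]])
    frames = np.repeat(pos[None], 3, axis=0)
    traj = make_traj(frames, geometry_config={"variant": "corridor", "b": 5.6, "l_c": 7.0})
    df = bs.density_timeseries(traj, corridor_56, MeasurementArea(), window=(0, 1))
    assert (df["rho"] < 0.2).all()
    # an agent outside the domain is rejected
    with pytest.raises(ValueError):
        voronoi_mean_density(np.array([[9.0, 3.0]]), corridor_56, MeasurementArea())


# -- Gaussian density field -------------------------------------------------


def test_gaussian_field_single_agent_mass_and_peak():
    frames = np.array([[[0.1, 3.0]]])
    traj = make_traj(frames, geometry_config={"variant": "corridor", "b": 4.0, "l_c": 7.0})
    field = gaussian_density_field(traj, a=0.3, spacing=0.05, window=(0, 0))
    assert field.integral() == pytest.approx(1.0, abs=0.01)
    iy, ix = np.unravel_index(np.argmax(field.values), field.values.shape)
    assert field.xs[ix] == pytest.approx(0.1, abs=0.05)
    assert field.ys[iy] == pytest.approx(3.0, abs=0.05)


def test_gaussian_field_two_distant_agents():
    frames = np.array([[[-1.5, 2.0], [1.5, 5.0]]])
    traj = make_traj(frames, geometry_config={"variant": "corridor", "b": 4.0, "l_c": 7.0})
    field = gaussian_density_field(traj, a=0.25, spacing=0.05, window=(0, 0))
    assert field.integral() == pytest.approx(2.0, abs=0.02)
    half = field.values[:, field.xs < 0.0]
    dx = field.xs[1] - field.xs[0]
    dy = field.ys[1] - field.ys[0]
    assert half.sum() * dx * dy == pytest.approx(1.0, abs=0.02)


def test_gaussian_field_matches_naive_double_loop():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0.5, 1.5, size=(3, 2))
    frames = np.repeat(pts[None], 2, axis=0)
    traj = make_traj(frames, dt=1.0, geometry_config={"variant": "corridor", "b": 4.0, "l_c": 2.0})
    a = 0.3
    field = gaussian_density_field(traj, a=a, spacing=0.1, window=(0, 1))
    xs, ys = field.xs, field.ys
    naive = np.zeros((len(ys), len(xs)))
    for iy in range(len(ys)):
        for ix in range(len(xs)):
            for x, y in pts:
                naive[iy, ix] += (
                    np.exp(-((xs[ix] - x) ** 2 + (ys[iy] - y) ** 2) / a**2)
                    / (np.pi * a**2)
                )
    np.testing.assert_allclose(field.values, naive, rtol=1e-9)


def test_gaussian_field_grid_spacing_guard():
    traj = make_traj(np.zeros((1, 1, 2)))
    with pytest.raises(ValueError):
        gaussian_density_field(traj, a=0.2, spacing=0.15)


# -- interaction angles -----------------------------------------------------


def test_follower_angle_zero(corridor_56, field_56):
    # two agents in single file above the exit: parallel desired directions
    frames = np.array([[[0.0, 1.0], [0.0, 0.5]]] * 25)
    traj = make_traj(frames, dt=0.5, geometry_config=corridor_56.config_dict())
    df = bs.interaction_angles(traj, field_56, ModelParams(), t_min=10.0)
    assert len(df) > 0
    assert np.abs(df["angle"]).max() < 2.0


def test_opposed_desired_directions_give_large_angle(corridor_56, field_56):
    # agents converging on the door from opposite flanks: desired
    # directions cross at a wide angle
    frames = np.array([[[-0.6, 0.35], [0.2, 0.3]]] * 25)
    traj = make_traj(frames, dt=0.5, geometry_config=corridor_56.config_dict())
    df = bs.interaction_angles(traj, field_56, ModelParams(), t_min=10.0)
    assert len(df) > 0
    assert df["angle"].max() > 100.0


def test_angle_histogram_contract():
    centers, probs = angle_histogram(np.full(100, 30.0), bin_width=5.0)
    assert probs.sum() == pytest.approx(1.0)
    assert probs[(centers > 25) & (centers < 35)].sum() == pytest.approx(1.0)
    modes = angle_modes(centers, probs, smooth_bins=1)
    assert modes[0][0] == pytest.approx(32.5)
    with pytest.raises(ValueError):
        angle_histogram([10.0], bin_width=7.0)


def test_angle_histogram_uniform_is_flat():
    rng = np.random.default_rng(0)
    centers, probs = angle_histogram(rng.uniform(0, 180, 200_000))
    assert probs.max() - probs.min() < 6 * np.sqrt(probs.mean() / 200_000) + 0.003


# -- waiting times and power law --------------------------------------------


def test_ballistic_walker_gives_alpha_one():
    # exact ballistic trajectory: r(t) = r0 - v0 t, so T_w = r/v0 and α = 1
    dt = 0.5
    v0 = 1.34
    r0 = 30.0
    n_frames = 60
    frames = np.array([[[0.0, r0 - v0 * dt * f]] for f in range(n_frames)])
    exit_t = r0 / v0
    traj = make_traj(frames, dt=dt, exit_times=[exit_t],
                     geometry_config={"variant": "corridor", "b": 2.0, "l_c": 35.0})
    wt = waiting_time_samples(traj, window=(10.0, 20.0), sample_interval=0.5)
    fit = fit_power_law(wt["r"], wt["T_w"], r_min=0.0, r_max=np.inf)
    assert fit.alpha == pytest.approx(1.0, abs=1e-9)


def test_waiting_time_sample_bookkeeping():
    # agent 0 exits at 12.2 s, agent 1 never exits, agent 2 exits before 10 s
    frames = np.repeat(np.array([[[0.0, 1.0], [0.5, 2.0], [0.0, 3.0]]]), 41, axis=0)
    traj = make_traj(frames, dt=0.5, exit_times=[12.2, np.nan, 8.0],
                     geometry_config={"variant": "corridor", "b": 2.0, "l_c": 7.0})
    wt = waiting_time_samples(traj, window=(10.0, 20.0), sample_interval=0.5)
    # direct recount oracle: agent 0 is sampled at t = 10, 10.5, ..., 12 only
    assert set(wt["agent"]) == {0}
    assert len(wt) == 5
    np.testing.assert_allclose(wt["T_w"], 12.2 - np.arange(10.0, 12.2, 0.5))


@pytest.mark.parametrize("alpha,pref", [(1.0, 0.7), (2.0, 2.0)])
def test_power_law_exact_recovery(alpha, pref):
    r = np.linspace(0.3, 1.5, 50)
    fit = fit_power_law(r, pref * r**alpha)
    assert fit.alpha == pytest.approx(alpha, abs=1e-12)
    assert fit.prefactor == pytest.approx(pref, rel=1e-9)


def test_power_law_noisy_recovery_within_stderr():
    rng = np.random.default_rng(0)
    r = rng.uniform(0.3, 1.5, 10_000)
    t_w = 3.0 * r**1.5 * rng.lognormal(0.0, 0.3, size=r.size)
    fit = fit_power_law(r, t_w)
    assert abs(fit.alpha - 1.5) < 3 * fit.alpha_stderr


def test_power_law_scale_covariance():
    rng = np.random.default_rng(1)
    r = rng.uniform(0.3, 1.5, 500)
    t_w = 2.0 * r**1.7 * rng.lognormal(0, 0.2, r.size)
    a1 = fit_power_law(r, t_w).alpha
    a2 = fit_power_law(r, 13.7 * t_w).alpha
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_power_law_too_few_samples():
    with pytest.raises(ValueError, match="[0-9]+ samples"):
        fit_power_law(np.array([0.5, 0.6]), np.array([1.0, 1.2]))


# -- exit gaps --------------------------------------------------------------


def test_exit_gaps_trimmed_mean():
    stats = exit_crossings_and_gaps(np.arange(1.0, 31.0), exclude=10)
    assert stats.mean_gap == pytest.approx(1.0)
    assert len(stats.gaps) == 9  # 10 kept crossings -> 9 gaps


def test_exit_gaps_edge_counts():
    stats = exit_crossings_and_gaps(np.arange(22, dtype=float), exclude=10)
    assert len(stats.gaps) == 1
    short = exit_crossings_and_gaps(np.arange(21, dtype=float), exclude=10)
    assert short.empty and np.isnan(short.mean_gap)


def test_n_t_curve_monotone():
    times = np.array([3.0, 1.0, np.nan, 2.0])
    df = n_t_curve(times)
    assert list(df["n_exited"]) == [1, 2, 3]
    assert (np.diff(df["t"]) >= 0).all()
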