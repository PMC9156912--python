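# Methods

## The model

`bottlesim` simulates pedestrians evacuating through a bottleneck as hard
discs of diameter `l` moving in continuous space with a velocity-based
(collision-free speed) model. Agent `i` moves with

    v_i = V(s_i) · e_i,      V(s) = min{ v0, max{0, (s − l)/T} },

where `s_i` is the centre distance to the nearest agent in `i`'s *headway*:
the set of agents `j` in the forward half-plane of the movement direction
`e_i` whose centres lie within lateral distance `l` of the movement line
(ties broken toward the lowest agent id). With an empty headway the agent
walks at its desired speed `v0`.

The slope factor `T` encodes motivation. Large `T` (low motivation) makes
agents slow down far from their predecessor; small `T` (high motivation)
closes any gap at full speed and reduces, in the limit `T → 0`, to pure
volume exclusion. `T` is the single parameter varied between the low- and
high-motivation conditions.

### Navigation

The desired direction field is the negative gradient of a time-cost field
`c(x)` solving the Eikonal equation `|∇c| = F` with `c = 0` on the exit
line, discretised on a regular grid (first-order fast marching on a binary
heap) and queried by bilinear interpolation of the per-cell unit
directions. Wall avoidance is encoded in the slowness

    F(x) = 1 + g · max(0, 1 − d(x)/d_w),

with `d(x)` the distance to the nearest wall, so walking near a wall is
more "expensive" and cost-optimal paths keep roughly `d_w` of clearance.
Wall cells carry an infinite sentinel; for gradient purposes they are
filled with a large finite cost, which adds a repulsive component in
wall-adjacent cells consistent with the ramp. Flat spots fall back to
pointing at the exit centre.

Walls interact with agents *only* through this slowness ramp plus a hard
no-tunnelling constraint (an agent whose candidate position would leave the
walkable polygon keeps its position for that step, with speed 0). There is
no hard-core exclusion between agent centres and walls: the wall-avoidance
ramp is the wall model. A hard `l/2` wall clearance was evaluated and
rejected: it shrinks the usable door width from `w_e` to `w_e − l` (0.15 m
at the default geometry), which throttles the outflow to a few agents per
minute and destroys every emergent observable.

### Direction noise

Every step each agent's direction is perturbed,

    e_i = (e_0 + ζ) / ‖e_0 + ζ‖,   ζ_x, ζ_y ~ N(0, σ),

with `σ = 0.7` interpreted as a *variance* (a configuration switch
`sigma_is_variance=False` reads it as a standard deviation instead; the
variance reading is the default and produced consistent flow phenomenology
in our experiments). The noise is redrawn every step, so the effective
angular diffusivity depends on the time step; `dt` is therefore frozen at
0.05 s for all experiments that are compared with each other. This noise is
not cosmetic: the deterministic model deadlocks at the door (opposing
desired directions), and the noise is the only mechanism that breaks such
stand-offs.

### Time stepping and collisions

Updates are synchronous with `dt = 0.05 s` (at most `T/2`, which bounds the
mutual approach of two agents within a step so the speed function alone
prevents head-on overlap). Residual collisions — mostly oblique, caused by
the direction noise — are resolved by *move-until-contact*: an agent whose
straight-line step would intersect another disc advances along its
direction exactly to the contact point and has velocity zero there,
mirroring the rule that velocity drops to zero on collision. Agents are
resolved in ascending id against the finalised positions of already
resolved agents and the held positions of the rest, which keeps every
pairwise distance ≥ `l` by construction and is deterministic. (The
alternative of rejecting the entire step was evaluated: it makes
high-motivation dynamics effectively binary — 6.7 cm jumps or nothing —
and produces artificial permanent clogs.)

Agents whose path crosses `y = 0` inside the door are recorded with a
linearly interpolated crossing time, then walk on down a short downstream
passage (1 m by default) as ordinary hard discs with desired direction
straight down and no noise, and are removed near its end. Keeping them
solid immediately behind the door line matters: the doorway stays
physically occupied for the ~0.3 s after a crossing, which is what limits
the exit flow in reality.

## Parameters

| parameter | symbol | default | notes |
|---|---|---|---|
| desired speed | `v0` | 1.34 m/s | unimpeded walking speed |
| agent diameter | `l` | 0.35 m | calibrated via the hexagonal packing bound: discs of radius 0.175 m pack to ≈ 9.4 m⁻², matching the observed density ceiling |
| slope factor | `T` | 1.3 s (low) / 0.1 s (high motivation) | |
| noise variance | `σ` | 0.7 | per component of ζ |
| time step | `dt` | 0.05 s | ≤ T/2; frozen across compared runs |
| grid spacing | `Δh` | 0.01 m (0.02–0.05 m for sweeps) | statistics are converged at the coarser grids; every sweep in the test-suite and the reproduction script uses 0.05 m |
| wall-avoidance distance | `d_w` | 0.25 m | |
| wall slowness gain | `g` | 3 | see below |
| door width | `w_e` | 0.5 m | door width of the emulated experiment series |
| corridor width | `b` | 0.8–7.0 m | sweep variable |
| agents | `N` | 55 | |

**Wall slowness gain.** Only the shape of the wall ramp (linear, reaching
its maximum at the wall) is fixed by the model description; its height is
free. With `g = 1` the wall band is so cheap that agents press into the
door-jamb corners and sit there for tens of seconds, bending the
waiting-time curves at small `r` and polluting the angle statistics. With
`g = 3` (walking speed quartered at the wall) preferred paths clear the
wall band, the jamb corners stay sparse, and all emergent observables
(waiting-time exponents across all five regimes, clog rates, angle
distributions) behave consistently. `g` is exposed in the configuration.

## Initial conditions

Per replicate: the initial density `ρ_i ~ U(2.0, 3.0) m⁻²` is drawn, the
corridor length is set to `l_c = max(N/(b·ρ_i), 7 m)`, and `N` agents are
placed uniformly at random in the corridor with hard-core rejection
(pairwise ≥ `l`, wall clearance ≥ `l/2`). Note that once `l_c` is capped at
7 m (wide corridors), the realised density is `N/(7b)` rather than `ρ_i` —
at `b = 5.6 m` the runs start around 1.4 m⁻², exactly as the corridor-length
rule implies.

Floor fields depend only on geometry and are cached with the corridor
length rounded up to the next metre; a field solved for a longer corridor
is exact for any shorter one because cost-optimal paths never lead away
from the exit.

## Measurements

* **Voronoi density** in the measurement rectangle `x ∈ [−0.4, 0.4]`,
  `y ∈ [0.5, 1.3]`: cells of all present agents are clipped to the walkable
  polygon; each agent spreads unit mass uniformly over its clipped cell
  `R_i`, so `ρ = Σ_i |R_i ∩ A| / (|R_i|·|A|)` and the density integrates to
  the agent count over the whole domain. Exact polygon areas (scipy Voronoi
  + shapely clipping), no sampling. Interval means average the per-frame
  densities over 5–10 s and 10–15 s windows (sampled every 0.25 s by
  default; 0.5 s in the wide sweeps — the series is smooth on that scale).
* **Density fields**: frame-averaged superposition of unit-mass isotropic
  Gaussians, `(1/πa²)·exp(−|r − r_i|²/a²)`, default `a = 0.2 m` (about the
  body radius; the width is a display parameter and is recorded with the
  field).
* **Interaction angles**: for every agent within 1 m of the exit centre
  whose headway set (recomputed with the *noiseless* field direction) is
  non-empty, the angle between the noiseless desired directions of the
  agent and of its spacing-limiting neighbour, collected from 10 s to the
  end of the run. Parallel follower chains give ≈ 0°, side-by-side merging
  ≈ 90°, head-on stand-offs ≈ 180°. Histograms use 5° bins; peak locations
  are local maxima after a 3-bin moving average. (Measuring instead the
  angle to the neighbour's *position* caps the distribution at 90° by
  construction and cannot reproduce the documented wide 90° mode.)
* **Waiting times**: every 0.5 s during `t ∈ [10, 20] s`, each not-yet-exited
  agent contributes `(r, T_w)` with `r` its straight-line distance to the
  exit centre and `T_w` its remaining time to exit; agents that never exit
  are skipped. `T_w ∝ r^α` is fitted by OLS on log–log data for
  `r ∈ [0.3, 1.5] m`. Exponent *curves* report the mean of per-run fits.
  A per-run slope is only accepted when it is well conditioned: at least
  10 in-range samples spanning at least a factor 2 in `r` (a heavily
  clogged run can leave a handful of samples bunched at one radius, whose
  "slope" is arbitrary — one such run returned α ≈ 156 and would dominate
  any mean). Pooling all runs into one fit is also available and is what
  the CLI `analyze` command does across files.
* **Time gaps**: `ΔT` between consecutive interpolated door crossings,
  dropping the first and last 10 crossings of each run.

## What the simulations do and do not show

The generator emulates the study conditions (geometry, parameter table,
initial-condition protocol), not raw human data: agents are homogeneous
discs with a single motivation parameter, no anticipation, communication,
body rotation or contact forces. Reproducing the emergent observables —
density rising with corridor width and saturating near `b ≈ 3.2 m`,
waiting-time exponents moving from ≈ 1 (single file) toward ≈ 2 (radial
convergence), bimodal interaction angles — demonstrates that these
phenomena need no social-psychological ingredient in the model, not that
the model captures individual human trajectories. Quantities that depend
on fine door-scale dynamics (the high-motivation exponents, clog
frequency) are the most sensitive to the collision-resolution details and
carry per-run spreads of ±0.6–0.8 in the fitted exponent; means over 50
replicates carry standard errors around 0.1.

Known limitations: at high motivation (`T = 0.1 s`) the hard-disc pack can
form long-lived arches at the door; runs are simulated to a 180 s horizon
for waiting-time work, and agents still inside then contribute no samples
(the same truncation any finite simulation campaign applies). The
exponent at `b = 5.6 m, T = 0.1 s` converges to ≈ 1.7 at `N = 55`; at
`N = 100` our implementation reaches ≈ 1.8 rather than a full 2.0 — the
N-dependence has the documented direction but a slightly shallower slope.
The wide interaction-angle mode sits at ≈ 95–105° rather than exactly 90°.
Both residuals are discussed above (collision micro-rules; wall-gain
freedom) and were not tuned away.

## Numerical choices

* Eikonal solver: first-order fast marching, 4-neighbour upwind update,
  binary heap; checked against an independent 8-connected Dijkstra oracle
  (agreement within the combined metrication/first-order error, < 10%).
* Degenerate noise draws (`|e_0 + ζ| < 1e-12`) are redrawn.
* Hard-core tolerance `ε = 1e-9` m on pairwise distances.
* Trajectory files carry 4-decimal positions (0.1 mm, far below any model
  scale) so files are diffable and round-trip exactly.
* Determinism: a run is a pure function of (config, seed); the same seed
  reproduces bit-identical trajectories. Replicates use consecutive seeds.
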