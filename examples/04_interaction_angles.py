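"""Interaction-angle distribution near the exit.

For every agent within 1 m of the door whose speed is limited by a
neighbour, measure the angle between the two agents' (noiseless) desired
directions. Followers give small angles; lanes merging side-on give wide
angles with high conflict potential.
"""

import numpy as np

import bottlesim as bs
from bottlesim.scenario import ScenarioConfig, iter_runs

cfg = ScenarioConfig(b=4.5, T=1.3, dh=0.05, horizon=120.0)
angles = []
for res in iter_runs(cfg, 4, base_seed=700):
    df = bs.interaction_angles(res.trajectory, res.floorfield, res.trajectory.params)
    angles.append(df["angle"].to_numpy())

centers, probs = bs.angle_histogram(np.concatenate(angles), bin_width=5.0)
modes = bs.angle_modes(centers, probs)
print("angle histogram (5 deg bins):")
for c, p in zip(centers, probs):
    print(f"{c:6.1f} deg  {'#' * int(300 * p)}")
print("modes:", [(round(c, 1), round(p, 3)) for c, p in modes])
print(
    "\nA narrow peak near 30 deg (followers in staggered lanes) and a wide\n"
    "peak in the 90-105 deg range (side-on merging at the door)."
)
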