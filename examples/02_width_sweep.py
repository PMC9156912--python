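"""Density versus corridor width: the counter-intuitive core result.

Wider corridors provide more space, yet the density in front of the
bottleneck *increases* with width until it saturates. This sweep
reproduces that curve at reduced replication (a few runs per width).
"""

import numpy as np

import bottlesim as bs
from bottlesim.geometry import MeasurementArea
from bottlesim.scenario import ScenarioConfig, iter_runs

print(f"{'b (m)':>6} {'rho 10-15 s (m^-2)':>20}")
for b in (0.8, 1.6, 2.4, 3.2, 4.0, 5.6, 7.0):
    cfg = ScenarioConfig(b=b, T=0.1, dh=0.05, horizon=15.05)
    vals = []
    for res in iter_runs(cfg, 5, base_seed=100 + int(10 * b)):
        df = bs.density_timeseries(
            res.trajectory, res.geometry, MeasurementArea(), (10, 15), 0.5
        )
        vals.append(df.attrs["mean"])
    print(f"{b:6.1f} {np.mean(vals):14.2f} +- {np.std(vals):.2f}")

print(
    "\nThe density rises with b and levels off around b = 3.2 m: once the\n"
    "corridor is wide enough, extra lanes merge far from the door and no\n"
    "longer compress the crowd in front of it."
)
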