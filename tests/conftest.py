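import numpy as np
import pytest

import bottlesim as bs


@pytest.fixture(scope="session")
def corridor_56():
    return bs.build_corridor(5.6, 7.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def corridor_12():
    return bs.build_corridor(1.2, 7.0, 0.5, 1.0)


@pytest.fixture(scope="session")
def field_56(corridor_56):
    """Coarse floor field for the 5.6 m corridor (shared, read-only)."""
    return bs.compute_floor_field(corridor_56, dh=0.05)


@pytest.fixture(scope="session")
def field_12(corridor_12):
    return bs.compute_floor_field(corridor_12, dh=0.05)


@pytest.fixture(scope="session")
def short_noisy_run(corridor_56, field_56):
    """A 10 s crowded run used by several invariant tests."""
    rng = np.random.default_rng(7)
    pos = bs.place_agents(corridor_56, 40, rng)
    params = bs.ModelParams(T=0.1, dt=0.05)
    return bs.run(corridor_56, field_56, params, pos, rng=rng, horizon=10.0)
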