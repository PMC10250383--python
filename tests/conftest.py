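import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import musselflow as mf

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def coastal():
    """Default two-block coastal scenario (field + habitat sites)."""
    cfg = mf.ScenarioConfig()
    field, sites = mf.coastal_scenario(cfg)
    return cfg, field, sites


@pytest.fixture(scope="session")
def small_grid():
    return mf.build_grid((600e3, 300e3), (5e3, 5e3), z_levels=(0.0, 10.0, 30.0))


@pytest.fixture(scope="session")
def solid_body(small_grid):
    return mf.solid_body_rotation(small_grid, 1e-4, (300e3, 150e3))


def rk4_orbit(field, start, dt_target, period):
    """Integrate one full period with steps dividing the period exactly."""
    n = int(np.ceil(period / dt_target))
    dt = period / n
    x, y, z = start
    for _ in range(n):
        x, y, z = mf.rk4_step((x, y, z), 0.0, dt, field)
    return x, y, z
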