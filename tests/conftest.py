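import numpy as np
import pandas as pd
import pytest

from urbangait.geo import M_PER_DEG
from urbangait.synthetic_world import GaitModel, generate_cohort, generate_zone_map


@pytest.fixture(scope="session")
def zone_map():
    return generate_zone_map(seed=1, n_rows=4, n_cols=4)


@pytest.fixture(scope="session")
def cohort(zone_map):
    return generate_cohort(seed=7, n=10, ci_fraction=0.4, zone_map=zone_map)


@pytest.fixture(scope="session")
def gait():
    return GaitModel()


@pytest.fixture(scope="session")
def gait_quiet():
    return GaitModel(noise_sd=0.0)


def make_straight_series(n, speed, dt=1.0, lon0=103.835, lat0=1.350, t0=0.0,
                         first_zero=False):
    """Constant-speed eastward walk; series speeds consistent with positions."""
    t = t0 + dt * np.arange(n)
    step_deg = speed * dt / (M_PER_DEG * np.cos(np.radians(lat0)))
    lon = lon0 + step_deg * np.arange(n)
    lat = np.full(n, lat0)
    sp = np.full(n, float(speed))
    if first_zero and n > 0:
        sp[0] = 0.0
    return pd.DataFrame({"t": t, "lat": lat, "lon": lon, "speed": sp,
                         "mode": np.where(sp < 1.39, "walking", "vehicular")})


@pytest.fixture
def straight_series():
    return make_straight_series
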