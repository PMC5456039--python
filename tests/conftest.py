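import numpy as np
import pandas as pd
import pytest

from arstrack import SimConfig, simulate_study, simulate_track


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_birds=4, trips_per_bird_range=(1, 3),
                     trip_range_km=(15, 30))


@pytest.fixture(scope="session")
def small_study(small_config):
    """A 4-bird study reused across tests (read-only)."""
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def single_day():
    """One single-day trip with a 1-km patch and its truth record."""
    cfg = SimConfig(seed=7, n_birds=1, trip_range_km=(30, 60))
    track, truth = simulate_track(cfg, 0, 0)
    return cfg, track, truth


def straight_track(n=51, spacing=100.0, speed=10.0, x0=0.0, y0=0.0, angle=0.0):
    """Constant-speed straight line as an interpolated-location frame."""
    s = spacing * np.arange(n)
    return pd.DataFrame({
        "x": x0 + s * np.cos(angle),
        "y": y0 + s * np.sin(angle),
        "t": s / speed,
        "colony_dist_m": s,
    })
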