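import numpy as np
import pandas as pd
import pytest

from aasarray import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced array/window that still exercises every stage."""
    return SimulationConfig(n_stations=4, n_hours=48, first_spawn_hour=30, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_sim():
    """The full default study conditions (6 stations, 158 h)."""
    return simulate_all(SimulationConfig(seed=12))


def make_hourcells(rng, J=3, H=8, max_v=12):
    """Small random HourCell table for model-encoding tests."""
    rows = []
    t0 = pd.Timestamp("2020-02-08T10:00:00")
    for j in range(J):
        for i in range(H):
            rows.append(
                {
                    "station_id": f"s{j}",
                    "hour_start": t0 + pd.Timedelta(hours=i),
                    "V": int(rng.integers(0, max_v)),
                    "tau": float(rng.uniform(0.4, 1.0)),
                    "T_index": int((10 + i) % 24),
                    "D_index": int(i % 7),
                    "FP_index": int(rng.integers(0, 3)),
                }
            )
    df = pd.DataFrame(rows)
    df["rate"] = df["V"] / df["tau"]
    return df
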