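import numpy as np
import pandas as pd
import pytest
import xarray as xr

import heatyield as hy


@pytest.fixture(scope="session")
def small_config():
    return hy.SyntheticConfig(
        n_cells_x=10, n_cells_y=6, n_units=60,
        years=range(2000, 2020), n_states=6, seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    weather = hy.generate_weather_grid(small_config)
    landscape = hy.generate_landscape(small_config)
    return weather, landscape


@pytest.fixture(scope="session")
def noisy_panel(small_config, small_world):
    weather, landscape = small_world
    thresholds = sorted({10.0, 29.0} | set(np.arange(24.0, 35.0)))
    return hy.generate_outcome_panel(
        weather, landscape, hy.TrueResponse(), small_config,
        thresholds=thresholds, compute_bins=True)


@pytest.fixture(scope="session")
def quiet_config(small_config):
    from dataclasses import replace
    return replace(small_config, noise_sd_logyield=0.0)


@pytest.fixture(scope="session")
def quiet_panel(quiet_config, small_world):
    weather, landscape = small_world
    return hy.generate_outcome_panel(
        weather, landscape, hy.TrueResponse(), quiet_config,
        thresholds=[10.0, 29.0], compute_bins=True)


def constant_weather(temp, n_days, years, prcp=0.0, ny=1, nx=1):
    """A toy weather grid held at a constant temperature every day."""
    chunks = []
    for yr in years:
        chunks.append(pd.date_range(f"{yr}-06-01", periods=n_days))
    times = pd.DatetimeIndex(np.concatenate([c.values for c in chunks]))
    shape = (len(times), ny, nx)
    return xr.Dataset(
        {
            "tmin": (("time", "y", "x"), np.full(shape, float(temp))),
            "tmax": (("time", "y", "x"), np.full(shape, float(temp))),
            "prcp": (("time", "y", "x"), np.full(shape, float(prcp))),
        },
        coords={"time": times, "y": np.arange(ny), "x": np.arange(nx)},
    )
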