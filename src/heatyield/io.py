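"""Plain-format readers and writers.

Gridded weather travels as NetCDF (dims time/y/x, variables tmin/tmax/prcp
in °C and mm; written through xarray's scipy backend as NETCDF3_CLASSIC) or
long CSV (cell_id, date, tmin, tmax, prcp).  Panels are flat CSVs with one
row per (unit, year).  Generator configuration is a YAML or TOML key-value
file mapping directly onto :class:`~heatyield.synthetic.SyntheticConfig`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .response import YieldPanel
from .synthetic import SyntheticConfig

__all__ = [
    "write_weather_netcdf", "read_weather_netcdf",
    "write_weather_csv", "read_weather_csv",
    "write_panel_csv", "read_panel_csv",
    "load_config",
]


def write_weather_netcdf(weather: xr.Dataset, path) -> None:
    weather.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def read_weather_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def write_weather_csv(weather: xr.Dataset, path) -> None:
    """Long format: one row per cell-day (cell ids row-major over y then x)."""
    ny, nx = weather.sizes["y"], weather.sizes["x"]
    nt = weather.sizes["time"]
    df = pd.DataFrame({
        "cell_id": np.tile(np.arange(ny * nx), nt),
        "date": np.repeat(pd.DatetimeIndex(weather["time"].values).strftime("%Y-%m-%d"),
                          ny * nx),
        "tmin": weather["tmin"].values.reshape(nt, -1).ravel(),
        "tmax": weather["tmax"].values.reshape(nt, -1).ravel(),
        "prcp": weather["prcp"].values.reshape(nt, -1).ravel(),
    })
    df.to_csv(path, index=False)


def read_weather_csv(path, ny: int, nx: int) -> xr.Dataset:
    df = pd.read_csv(path, parse_dates=["date"])
    times = pd.DatetimeIndex(df["date"].unique())
    nt = len(times)
    data = {}
    for var in ("tmin", "tmax", "prcp"):
        data[var] = (("time", "y", "x"),
                     df[var].to_numpy().reshape(nt, ny, nx))
    return xr.Dataset(data, coords={"time": times,
                                    "y": np.arange(ny), "x": np.arange(nx)})


def write_panel_csv(panel: YieldPanel, path) -> None:
    """One row per (unit, year); degree-day columns named ``dd_above_<b>``."""
    out = panel.df.copy()
    for j, b in enumerate(panel.thresholds):
        out[f"dd_above_{b:g}"] = panel.dd[:, j]
    out.to_csv(path, index=False)


def read_panel_csv(path) -> YieldPanel:
    df = pd.read_csv(path)
    dd_cols = sorted((c for c in df.columns if c.startswith("dd_above_")),
                     key=lambda c: float(c.removeprefix("dd_above_")))
    thresholds = np.array([float(c.removeprefix("dd_above_")) for c in dd_cols])
    dd = df[dd_cols].to_numpy(dtype=float)
    return YieldPanel(df=df.drop(columns=dd_cols), dd=dd, thresholds=thresholds)


def load_config(path) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a YAML (or TOML) key-value file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        raw = tomllib.loads(path.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "years" in raw:
        raw["years"] = [int(y) for y in raw["years"]]
    if "season" in raw:
        raw["season"] = tuple(int(d) for d in raw["season"])
    if "temp_mean_profile" in raw:
        raw["temp_mean_profile"] = tuple(float(v) for v in raw["temp_mean_profile"])
    return SyntheticConfig(**raw)
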