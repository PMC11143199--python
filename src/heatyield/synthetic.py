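"""Synthetic weather grids, landscapes, and outcome panels with known truth.

Every downstream stage — exposure construction, crop-weighted aggregation,
fixed-effects estimation, cross-validated model comparison, warming
projections — is exercised against data whose generating process is fully
known, so recovery of the truth is a testable property rather than a hope.

The generator emulates the statistical structure the analysis assumes:

* daily Tmin/Tmax fields with a seasonal cycle, AR(1) day-to-day
  persistence, Gaussian-kernel spatial correlation, and a positive diurnal
  range (so Tmax ≥ Tmin by construction); gamma-distributed daily
  precipitation;
* a landscape of contiguous rectangular units ("counties") nested in
  "states" (trend/cluster groups) and "countries", with crop-share weights
  per cell and weather-station flags concentrated in a configurable subset
  of countries (as station networks are in practice);
* log outcomes (yield, or a season-total vegetation-index analogue) built
  from a known piecewise-linear heat response, a quadratic precipitation
  effect, unit fixed effects, group-specific quadratic trends, and Gaussian
  noise.

With ``noise_sd_logyield = 0`` outcomes lie exactly in the span of the true
regressors, so estimators must recover the truth to numerical precision.
The defaults are stand-ins for field data whose distribution is not
published; they are documented, not estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, signal

from .aggregation import WeightMatrix, build_weights_centroid, build_weights_overlap
from .pipeline import cell_season_panel
from .response import YieldPanel

__all__ = ["SyntheticConfig", "TrueResponse", "Landscape",
           "generate_weather_grid", "generate_landscape", "generate_outcome_panel"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; ``seed`` fixes all randomness."""

    n_cells_x: int = 25
    n_cells_y: int = 20
    n_units: int = 500
    years: Sequence[int] = tuple(range(1990, 2020))
    season: tuple[int, int] = (60, 273)          # day-of-year window [start, end)
    temp_mean_profile: tuple[float, float, float] = (12.0, 14.0, 200.0)
    # (annual mean °C, seasonal amplitude °C, peak day of year)
    diurnal_range_mean: float = 10.0             # °C, mean of tmax - tmin
    temp_anom_sd: float = 4.0                    # °C, sd of daily mean anomalies
    spatial_corr_length: float = 2.0             # cells, Gaussian kernel scale
    ar1_coef: float = 0.7                        # daily persistence of anomalies
    precip_shape: float = 0.5                    # gamma shape of daily totals
    precip_scale_mm: float = 5.0                 # gamma scale, mm
    noise_sd_logyield: float = 0.2               # log points
    n_states: int = 20
    n_countries: int = 10
    station_frac: float = 0.02                   # stations per cell
    station_countries: int = 2                   # countries hosting the bulk
    station_share: float = 0.7                   # share of stations they host
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_x <= 0 or self.n_cells_y <= 0:
            raise ValueError("grid dimensions must be positive")
        if len(self.years) == 0:
            raise ValueError("year list must be non-empty")
        if self.diurnal_range_mean <= 0:
            raise ValueError("diurnal_range_mean must be positive")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.season[0] >= self.season[1]:
            raise ValueError("season start must precede season end")
        if self.n_units > self.n_cells_x * self.n_cells_y:
            raise ValueError("n_units cannot exceed the number of cells")

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y

    @property
    def season_length(self) -> int:
        return self.season[1] - self.season[0]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per stage, all derived from ``seed``."""
        return np.random.default_rng([stream, self.seed])


@dataclass
class TrueResponse:
    """Ground-truth response: the asymmetric piecewise heat effect plus a
    concave precipitation effect.  Default slopes are order-of-magnitude
    plausible for row crops and synthetic, not estimates: moderate heat helps
    a little per degree day, extreme heat hurts an order of magnitude more.
    """

    breakpoint: float = 29.0
    slope_moderate: float = 4.0e-4    # Δ log yield per moderate degree day
    slope_extreme: float = -6.0e-3    # Δ log yield per extreme degree day
    base: float = 10.0
    precip_lin: float = 0.02          # per cm (optimum at 50 cm with quad below)
    precip_quad: float = -2.0e-4      # per cm²
    trend_coefs: np.ndarray | None = None   # (n_groups, 2): linear, quadratic
    unit_effects: np.ndarray | None = None  # (n_units,)
    unit_effect_sd: float = 0.3
    trend_lin_mean: float = 0.015
    trend_lin_sd: float = 0.005
    trend_quad_sd: float = 2.0e-4

    def __post_init__(self) -> None:
        for v in (self.breakpoint, self.slope_moderate, self.slope_extreme,
                  self.precip_lin, self.precip_quad):
            if not np.isfinite(v):
                raise ValueError("response parameters must be finite")


@dataclass
class Landscape:
    """Cell-to-unit geometry, crop weights, groupings, and station flags."""

    unit_of_cell: np.ndarray          # (n_cells,)
    overlaps: pd.DataFrame            # cell, unit, fraction
    crop_share: np.ndarray            # (n_cells,)
    station: np.ndarray               # (n_cells,) bool
    state_of_unit: np.ndarray         # (n_units,)
    country_of_unit: np.ndarray       # (n_units,)
    n_units: int

    @property
    def country_of_cell(self) -> np.ndarray:
        return self.country_of_unit[self.unit_of_cell]

    def weights(self, method: str = "centroid") -> WeightMatrix:
        if method == "centroid":
            return build_weights_centroid(self.unit_of_cell, self.crop_share,
                                          self.n_units)
        if method == "overlap":
            return build_weights_overlap(self.overlaps, self.crop_share,
                                         self.n_units)
        raise ValueError("method must be 'centroid' or 'overlap'")

    def unit_meta(self, level: str = "unit") -> pd.DataFrame:
        """Per-unit (or per-cell) grouping table for panel construction."""
        if level == "unit":
            return pd.DataFrame({
                "cluster_group": self.state_of_unit,
                "trend_group": self.state_of_unit,
                "country": self.country_of_unit,
            }, index=pd.Index(np.arange(self.n_units), name="unit"))
        return pd.DataFrame({
            "cluster_group": self.country_of_cell,
            "trend_group": self.country_of_cell,
            "country": self.country_of_cell,
            "station": self.station,
        }, index=pd.Index(np.arange(len(self.unit_of_cell)), name="unit"))


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def _season_times(config: SyntheticConfig) -> pd.DatetimeIndex:
    start, end = config.season
    chunks = [
        pd.Timestamp(f"{yr}-01-01") + pd.to_timedelta(np.arange(start - 1, end - 1), "D")
        for yr in config.years
    ]
    return pd.DatetimeIndex(np.concatenate([c.values for c in chunks]))


def _correlated_anomalies(config: SyntheticConfig, rng, n_time) -> np.ndarray:
    """AR(1)-in-time, spatially smoothed unit-variance anomaly field."""
    shape = (n_time, config.n_cells_y, config.n_cells_x)
    eps = rng.standard_normal(shape)
    if config.spatial_corr_length > 0:
        eps = ndimage.gaussian_filter(
            eps, sigma=config.spatial_corr_length, axes=(1, 2), mode="nearest")
        eps /= eps.std()
    rho = config.ar1_coef
    if rho > 0:
        sl = config.season_length
        eps = eps.reshape(len(config.years), sl, -1)
        innov = eps * np.sqrt(1.0 - rho ** 2)
        innov[:, 0, :] = eps[:, 0, :]          # stationary start each season
        eps = signal.lfilter([1.0], [1.0, -rho], innov, axis=1)
        eps = eps.reshape(shape)
    return eps


def generate_weather_grid(config: SyntheticConfig) -> xr.Dataset:
    """Daily Tmin/Tmax (°C) and precipitation (mm) for every growing season.

    Daily mean temperature is a seasonal cosine plus correlated anomalies;
    the (gamma-distributed, hence positive) diurnal range is split evenly
    around it, so Tmax ≥ Tmin always.  Same config, same seed → bit-identical
    output.
    """
    rng = config.rng(0)
    times = _season_times(config)
    n_time = len(times)
    mean, amp, peak = config.temp_mean_profile
    doy = times.dayofyear.values.astype(float)
    seasonal = mean + amp * np.cos(2.0 * np.pi * (doy - peak) / 365.25)

    anom = _correlated_anomalies(config, rng, n_time)
    tmid = seasonal[:, None, None] + config.temp_anom_sd * anom

    k = 10.0  # shape of the diurnal-range gamma: sd ≈ mean/√10
    drange = rng.gamma(k, config.diurnal_range_mean / k,
                       size=(n_time, config.n_cells_y, config.n_cells_x))
    prcp = rng.gamma(config.precip_shape, config.precip_scale_mm,
                     size=(n_time, config.n_cells_y, config.n_cells_x))

    coords = {"time": times, "y": np.arange(config.n_cells_y),
              "x": np.arange(config.n_cells_x)}
    ds = xr.Dataset(
        {
            "tmin": (("time", "y", "x"), tmid - 0.5 * drange, {"units": "degC"}),
            "tmax": (("time", "y", "x"), tmid + 0.5 * drange, {"units": "degC"}),
            "prcp": (("time", "y", "x"), prcp, {"units": "mm"}),
        },
        coords=coords,
    )
    return ds


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _balanced_factors(n: int) -> tuple[int, int]:
    a = int(np.floor(np.sqrt(n)))
    while n % a:
        a -= 1
    return a, n // a


def generate_landscape(config: SyntheticConfig) -> Landscape:
    """Contiguous rectangular units nested in states and countries, with crop
    shares and station flags concentrated in a few countries."""
    rng = config.rng(1)
    ny, nx = config.n_cells_y, config.n_cells_x
    a, b = _balanced_factors(config.n_units)
    if a > ny or b > nx:
        a, b = b, a
    row_blocks = np.concatenate([np.full(len(ch), i) for i, ch in
                                 enumerate(np.array_split(np.arange(ny), a))])
    col_blocks = np.concatenate([np.full(len(ch), j) for j, ch in
                                 enumerate(np.array_split(np.arange(nx), b))])
    unit_grid = row_blocks[:, None] * b + col_blocks[None, :]
    unit_of_cell = unit_grid.ravel()

    state_of_unit = np.concatenate([
        np.full(len(ch), i) for i, ch in
        enumerate(np.array_split(np.arange(config.n_units), config.n_states))])
    country_of_unit = np.concatenate([
        np.full(len(ch), i) for i, ch in
        enumerate(np.array_split(np.arange(config.n_units), config.n_countries))])

    crop_share = rng.beta(2.0, 2.0, size=config.n_cells)

    country_of_cell = country_of_unit[unit_of_cell]
    n_stations = max(1, round(config.station_frac * config.n_cells))
    host = np.arange(min(config.station_countries, config.n_countries))
    in_host = np.flatnonzero(np.isin(country_of_cell, host))
    out_host = np.flatnonzero(~np.isin(country_of_cell, host))
    n_in = min(round(config.station_share * n_stations), len(in_host))
    n_out = min(n_stations - n_in, len(out_host))
    station = np.zeros(config.n_cells, dtype=bool)
    station[rng.choice(in_host, n_in, replace=False)] = True
    if n_out > 0:
        station[rng.choice(out_host, n_out, replace=False)] = True

    overlaps = pd.DataFrame({
        "cell": np.arange(config.n_cells),
        "unit": unit_of_cell,
        "fraction": np.ones(config.n_cells),
    })
    return Landscape(unit_of_cell, overlaps, crop_share, station,
                     state_of_unit, country_of_unit, config.n_units)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def generate_outcome_panel(
    weather: xr.Dataset,
    landscape: Landscape,
    truth: TrueResponse,
    config: SyntheticConfig,
    level: str = "unit",
    thresholds=None,
    compute_bins: bool = False,
    weight_method: str = "centroid",
) -> YieldPanel:
    """Outcome panel from the known response applied to true exposures.

    Exposures are computed at cell level (preserving the nonlinearity) and
    aggregated with crop-share weights before the response is applied, so the
    panel is exactly what the estimation modules assume.  ``level="cell"``
    yields the vegetation-index variant: one series per grid cell with
    country groupings and station flags (the data-sparse-region design).
    """
    if thresholds is None:
        thresholds = [truth.base, truth.breakpoint]
    thresholds = sorted({float(t) for t in
                         list(np.atleast_1d(thresholds)) + [truth.base, truth.breakpoint]})
    season = cell_season_panel(weather, thresholds, compute_bins=compute_bins)
    if level == "unit":
        season = season.aggregate(landscape.weights(weight_method))
        groups = landscape.state_of_unit[season.ids]
        n_units = len(season.ids)
    elif level == "cell":
        groups = landscape.country_of_cell
        n_units = season.n_locations
    else:
        raise ValueError("level must be 'unit' or 'cell'")

    rng = config.rng(2)
    if truth.unit_effects is None:
        unit_effects = rng.normal(0.0, truth.unit_effect_sd, n_units)
    else:
        unit_effects = np.asarray(truth.unit_effects, dtype=float)
        if unit_effects.shape != (n_units,):
            raise ValueError(f"unit_effects must have shape ({n_units},)")
    n_groups = int(groups.max()) + 1
    if truth.trend_coefs is None:
        trend_coefs = np.column_stack([
            rng.normal(truth.trend_lin_mean, truth.trend_lin_sd, n_groups),
            rng.normal(0.0, truth.trend_quad_sd, n_groups),
        ])
    else:
        trend_coefs = np.asarray(truth.trend_coefs, dtype=float)

    mod = season.dd_above(truth.base) - season.dd_above(truth.breakpoint)
    ext = season.dd_above(truth.breakpoint)
    P = season.prcp_cm
    ty = (season.years - season.years.mean())[:, None]
    y = (unit_effects[None, :]
         + trend_coefs[groups, 0][None, :] * ty
         + trend_coefs[groups, 1][None, :] * ty ** 2
         + truth.precip_lin * P + truth.precip_quad * P ** 2
         + truth.slope_moderate * mod + truth.slope_extreme * ext)
    if config.noise_sd_logyield > 0:
        y = y + rng.normal(0.0, config.noise_sd_logyield, y.shape)
    if config.missing_rate > 0:
        drop = rng.random(y.shape) < config.missing_rate
        y = np.where(drop, np.nan, y)

    panel = YieldPanel.from_season_panel(season, y, landscape.unit_meta(level))
    return panel
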