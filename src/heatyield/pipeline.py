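"""Vectorized seasonal exposure panels from gridded daily weather.

Bridges the day-level closed forms in :mod:`heatyield.exposure` and the
panel estimators: takes an xarray Dataset of daily ``tmin``/``tmax``/``prcp``
on a (time, y, x) grid, computes cell-level seasonal degree days, bin
exposures, precipitation totals and mean temperature for every year, and
aggregates them to administrative units with a :class:`~heatyield.aggregation.WeightMatrix`.

All nonlinear transforms happen at cell level before any spatial averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .aggregation import WeightMatrix, aggregate_exposure
from .exposure import default_bin_edges, degree_days_sine, fraction_above_sine

__all__ = ["SeasonPanel", "cell_season_panel"]


@dataclass
class SeasonPanel:
    """Seasonal weather covariates for a set of locations (cells or units) × years.

    Arrays are indexed ``[year, location]`` (and a trailing axis for degree-day
    thresholds / exposure bins).  ``exposure`` covers the core 1 °C bins;
    exposure outside the tabulated range is kept in ``exp_below``/``exp_above``.
    """

    years: np.ndarray                 # (m,)
    ids: np.ndarray                   # (n,) location labels
    thresholds: np.ndarray            # (K,)
    dd: np.ndarray                    # (m, n, K) degree days above each threshold
    prcp_cm: np.ndarray               # (m, n) season-total precipitation, cm
    tmean: np.ndarray                 # (m, n) season mean of monthly mean temperature
    season_days: np.ndarray           # (m,) day count per year
    bin_edges: np.ndarray | None = None
    exposure: np.ndarray | None = None    # (m, n, n_bins)
    exp_below: np.ndarray | None = None   # (m, n)
    exp_above: np.ndarray | None = None   # (m, n)
    level: str = "cell"

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_locations(self) -> int:
        return len(self.ids)

    def dd_above(self, threshold: float) -> np.ndarray:
        """Degree days above one of the precomputed thresholds, shape (m, n)."""
        idx = np.flatnonzero(np.isclose(self.thresholds, threshold))
        if idx.size == 0:
            raise KeyError(
                f"threshold {threshold} not precomputed; available: {self.thresholds}")
        return self.dd[:, :, idx[0]]

    def aggregate(self, W: WeightMatrix) -> "SeasonPanel":
        """Crop/overlap-weighted mean over cells for every unit (linear, so it
        preserves the already-computed nonlinear transforms)."""
        if self.level != "cell":
            raise ValueError("panel already aggregated")
        act = W.active()
        out = replace(
            self,
            ids=act.unit_ids,
            dd=aggregate_exposure(self.dd, W),
            prcp_cm=aggregate_exposure(self.prcp_cm, W),
            tmean=aggregate_exposure(self.tmean, W),
            level="unit",
        )
        if self.exposure is not None:
            out.exposure = aggregate_exposure(self.exposure, W)
            out.exp_below = aggregate_exposure(self.exp_below, W)
            out.exp_above = aggregate_exposure(self.exp_above, W)
        return out


def cell_season_panel(
    weather: xr.Dataset,
    thresholds,
    bin_edges=None,
    compute_bins: bool = False,
) -> SeasonPanel:
    """Seasonal exposure panel for every grid cell and year in ``weather``.

    ``weather`` must carry daily ``tmin``, ``tmax`` (°C) and ``prcp`` (mm)
    on dims (time, y, x); the time axis is assumed to already be restricted
    to the growing-season window of each year.  Degree days use the sine
    interpolation between the daily extremes; ``compute_bins`` additionally
    tabulates the 1 °C time-in-bin exposure needed by the polynomial and
    bin regressors.
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    time = pd.DatetimeIndex(weather["time"].values)
    years = np.unique(time.year)
    ny, nx = weather.sizes["y"], weather.sizes["x"]
    n_cells = ny * nx
    cell_ids = np.arange(n_cells)

    tmin = weather["tmin"].values.reshape(len(time), n_cells)
    tmax = weather["tmax"].values.reshape(len(time), n_cells)
    prcp = weather["prcp"].values.reshape(len(time), n_cells)
    if np.any(tmax < tmin):
        raise ValueError("weather contains days with tmax < tmin")

    year_idx = np.searchsorted(years, time.year.values)
    m = len(years)
    season_days = np.bincount(year_idx, minlength=m).astype(float)

    # degree days: closed form per day, summed within year
    dd = np.empty((m, n_cells, thresholds.size))
    for k, b in enumerate(thresholds):
        daily = degree_days_sine(tmin, tmax, threshold=b)
        for j in range(m):
            dd[j, :, k] = daily[year_idx == j].sum(axis=0)

    # precipitation: season total in cm
    prcp_cm = np.empty((m, n_cells))
    for j in range(m):
        prcp_cm[j] = prcp[year_idx == j].sum(axis=0) / 10.0

    # T_it: monthly means of the daily midpoint, averaged over season months
    tmid = 0.5 * (tmin + tmax)
    key = time.year.values * 100 + time.month.values
    tmean = np.empty((m, n_cells))
    frame = pd.DataFrame(tmid)
    monthly = frame.groupby(key).mean()
    myears = monthly.index.to_numpy() // 100
    for j, yr in enumerate(years):
        tmean[j] = monthly.to_numpy()[myears == yr].mean(axis=0)

    panel = SeasonPanel(
        years=years, ids=cell_ids, thresholds=thresholds, dd=dd,
        prcp_cm=prcp_cm, tmean=tmean, season_days=season_days,
    )

    if compute_bins:
        if bin_edges is None:
            bin_edges = default_bin_edges()
        bin_edges = np.asarray(bin_edges, dtype=float)
        nb = bin_edges.size - 1
        exposure = np.zeros((m, n_cells, nb))
        below = np.zeros((m, n_cells))
        above = np.zeros((m, n_cells))
        for j in range(m):  # per-year blocks keep the edge × day array small
            sel = year_idx == j
            fa = fraction_above_sine(tmin[sel, :, None], tmax[sel, :, None],
                                     bin_edges[None, None, :])
            exposure[j] = np.maximum(fa[:, :, :-1] - fa[:, :, 1:], 0.0).sum(axis=0)
            below[j] = (1.0 - fa[:, :, 0]).sum(axis=0)
            above[j] = fa[:, :, -1].sum(axis=0)
        panel.bin_edges = bin_edges
        panel.exposure = exposure
        panel.exp_below = below
        panel.exp_above = above

    return panel
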