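"""Within-day temperature exposure and degree days.

Crop damage from heat is driven by *how long* and *by how much* temperature
exceeds critical levels within each day, not by daily or monthly averages.
This module converts raw temperature records — daily (tmin, tmax) pairs,
hourly series, or monthly summaries — into two exposure measures:

* the time (fraction of a day) spent in each 1 °C interval, accumulated over
  a growing season into an :class:`ExposureDistribution`;
* degree days above a threshold ``b``: the time integral of ``max(T - b, 0)``
  in °C·days. A day at constant ``b + k`` contributes ``k`` degree days.

For daily extremes the within-day path is modelled as a single sine wave
``T(t) = M + W sin(2πt)`` with midpoint ``M = (tmax + tmin)/2`` and amplitude
``W = (tmax - tmin)/2``; both exposure measures then have closed forms.  For
monthly mean/sd summaries, degree days follow the Thom normal approximation.
A quantile-matching infill for gappy station records is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_BIN_LO",
    "DEFAULT_BIN_HI",
    "DayWeather",
    "ExposureDistribution",
    "SeasonWeather",
    "default_bin_edges",
    "fraction_above_sine",
    "degree_days_sine",
    "fraction_above_double_sine",
    "degree_days_double_sine",
    "day_bin_exposure_sine",
    "day_exposure_hourly",
    "degree_days_hourly",
    "thom_degree_days",
    "accumulate_season",
    "quantile_infill",
]

# Exposure is tabulated on 1 °C half-open bins [h, h+1) for h = -4 ... 41,
# with open overflow bins below/above; the full observed range is retained,
# overflow is folded into the edge bins only when building regressors.
DEFAULT_BIN_LO = -4
DEFAULT_BIN_HI = 42

_TWO_PI = 2.0 * np.pi


def default_bin_edges() -> np.ndarray:
    """Integer bin edges -4, -3, ..., 42 (46 one-degree bins)."""
    return np.arange(DEFAULT_BIN_LO, DEFAULT_BIN_HI + 1, dtype=float)


@dataclass(frozen=True)
class DayWeather:
    """One day's temperature record: (tmin, tmax) extremes or 24 hourly values."""

    tmin: float | None = None
    tmax: float | None = None
    hourly: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hourly is not None:
            h = np.asarray(self.hourly, dtype=float)
            if h.shape != (24,):
                raise ValueError(f"hourly record must have 24 values, got {h.shape}")
            if not np.all(np.isfinite(h)):
                raise ValueError("hourly record contains non-finite values")
            object.__setattr__(self, "hourly", h)
        else:
            if self.tmin is None or self.tmax is None:
                raise ValueError("provide either (tmin, tmax) or an hourly record")
            if self.tmax < self.tmin:
                raise ValueError(f"tmax ({self.tmax}) < tmin ({self.tmin})")


@dataclass
class ExposureDistribution:
    """Season-cumulative time (days) spent in each 1 °C temperature interval.

    ``time_in_bin[j]`` is the time spent in ``[bin_edges[j], bin_edges[j+1])``;
    ``below``/``above`` hold exposure outside the tabulated range.  The grand
    total equals the number of (possibly fractional) days accumulated.
    """

    bin_edges: np.ndarray = field(default_factory=default_bin_edges)
    time_in_bin: np.ndarray | None = None
    below: float = 0.0
    above: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.time_in_bin is None:
            self.time_in_bin = np.zeros(len(self.bin_edges) - 1)
        else:
            self.time_in_bin = np.asarray(self.time_in_bin, dtype=float)
        if len(self.time_in_bin) != len(self.bin_edges) - 1:
            raise ValueError("time_in_bin length must be len(bin_edges) - 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_days(self) -> float:
        return float(self.time_in_bin.sum() + self.below + self.above)

    def folded(self) -> np.ndarray:
        """Core bin masses with the overflow folded into the edge bins."""
        t = self.time_in_bin.copy()
        t[0] += self.below
        t[-1] += self.above
        return t

    def __add__(self, other: "ExposureDistribution") -> "ExposureDistribution":
        if not np.array_equal(self.bin_edges, other.bin_edges):
            raise ValueError("cannot add exposures on different bin grids")
        return ExposureDistribution(
            bin_edges=self.bin_edges,
            time_in_bin=self.time_in_bin + other.time_in_bin,
            below=self.below + other.below,
            above=self.above + other.above,
        )


# ---------------------------------------------------------------------------
# Sine interpolation between daily extremes
# ---------------------------------------------------------------------------

def fraction_above_sine(tmin, tmax, level) -> np.ndarray | float:
    """Fraction of a day the sine path ``M + W sin(2πt)`` spends above ``level``.

    Closed form ``(π - 2 asin((level - M)/W)) / (2π)`` on the interior, 0/1
    outside; a constant day (W = 0) counts as above iff ``M >= level``.
    Broadcasts over array inputs.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    level = np.asarray(level, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    M = 0.5 * (tmax + tmin)
    W = 0.5 * (tmax - tmin)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.clip((level - M) / np.where(W > 0, W, np.inf), -1.0, 1.0)
    frac = (np.pi - 2.0 * np.arcsin(a)) / _TWO_PI
    frac = np.where(level <= tmin, 1.0, frac)
    frac = np.where(level > tmax, 0.0, frac)
    # degenerate constant day: all-or-nothing at the day's temperature
    const = W == 0
    if np.any(const):
        frac = np.where(const, (M >= level).astype(float), frac)
    out = np.clip(frac, 0.0, 1.0)
    return out if out.ndim else float(out)


def degree_days_sine(day, tmax=None, *, threshold) -> np.ndarray | float:
    """Degree days above ``threshold`` for a sine day between tmin and tmax.

    Accepts ``degree_days_sine(DayWeather(...), threshold=b)`` or
    ``degree_days_sine(tmin, tmax, threshold=b)`` with array broadcasting.

    Piecewise closed form with ``θ = asin((b - M)/W)``::

        0                                   if tmax <= b
        M - b                               if tmin >= b
        [(M - b)(π/2 - θ) + W cos θ] / π    otherwise
    """
    if isinstance(day, DayWeather):
        if day.hourly is not None:
            raise TypeError("use degree_days_hourly for hourly records")
        tmin, tmax = day.tmin, day.tmax
    else:
        tmin = day
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    b = np.asarray(threshold, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    M = 0.5 * (tmax + tmin)
    W = 0.5 * (tmax - tmin)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arcsin(np.clip((b - M) / np.where(W > 0, W, np.inf), -1.0, 1.0))
    interior = ((M - b) * (np.pi / 2.0 - theta) + W * np.cos(theta)) / np.pi
    dd = np.where(tmax <= b, 0.0, np.where(tmin >= b, M - b, interior))
    out = np.maximum(dd, 0.0)
    return out if out.ndim else float(out)


def day_bin_exposure_sine(day, tmax=None, bin_edges=None) -> ExposureDistribution:
    """Time-in-bin exposure for one day under the sine interpolation.

    Fractions are differences of the closed-form time-above curve at
    consecutive bin edges, so they are nonnegative and sum to 1 exactly.
    """
    if isinstance(day, DayWeather):
        if day.hourly is not None:
            return day_exposure_hourly(day.hourly, bin_edges)
        tmin, tmax = day.tmin, day.tmax
    else:
        tmin = day
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    above = fraction_above_sine(tmin, tmax, bin_edges)
    frac = above[:-1] - above[1:]
    return ExposureDistribution(
        bin_edges=bin_edges,
        time_in_bin=np.maximum(frac, 0.0),
        below=float(1.0 - above[0]),
        above=float(above[-1]),
    )


def fraction_above_double_sine(tmin, tmax, next_tmin, level):
    """Time-above for the double-sine day: rise tmin→tmax as a half sine,
    fall tmax→``next_tmin`` (the following day's minimum) as another.

    Each monotone half-sine spends the same fraction of its half-day above a
    level as a full sine with the same endpoints, so the day is the equal-
    weight average of two single-sine days.  ``next_tmin`` is capped at
    ``tmax`` so the falling half is well defined.
    """
    nt = np.minimum(np.asarray(next_tmin, dtype=float), np.asarray(tmax, dtype=float))
    return 0.5 * (np.asarray(fraction_above_sine(tmin, tmax, level))
                  + fraction_above_sine(nt, tmax, level))


def degree_days_double_sine(tmin, tmax, next_tmin, *, threshold):
    """Degree days for the double-sine day (rise to tmax, fall to the next
    day's minimum); average of the two single-sine closed forms."""
    nt = np.minimum(np.asarray(next_tmin, dtype=float), np.asarray(tmax, dtype=float))
    return 0.5 * (np.asarray(degree_days_sine(tmin, tmax, threshold=threshold))
                  + degree_days_sine(nt, tmax, threshold=threshold))


# ---------------------------------------------------------------------------
# Hourly records
# ---------------------------------------------------------------------------

def day_exposure_hourly(hourly, bin_edges=None) -> ExposureDistribution:
    """Each hour contributes 1/24 day to the 1 °C bin containing it."""
    h = np.asarray(hourly, dtype=float)
    if h.shape != (24,):
        raise ValueError(f"hourly record must have 24 values, got {h.shape}")
    if not np.all(np.isfinite(h)):
        raise ValueError("hourly record contains non-finite values")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(h, bins=bin_edges)
    below = float(np.sum(h < bin_edges[0]))
    above = float(np.sum(h >= bin_edges[-1]))
    return ExposureDistribution(
        bin_edges=bin_edges,
        time_in_bin=counts / 24.0,
        below=below / 24.0,
        above=above / 24.0,
    )


def degree_days_hourly(hourly, threshold) -> float:
    """Degree days from an hourly record: mean hourly excess above threshold."""
    h = np.asarray(hourly, dtype=float)
    if h.shape[-1] != 24:
        raise ValueError("hourly record must have 24 values")
    if not np.all(np.isfinite(h)):
        raise ValueError("hourly record contains non-finite values")
    dd = np.maximum(h - float(threshold), 0.0).sum(axis=-1) / 24.0
    return float(dd) if np.ndim(dd) == 0 else dd


# ---------------------------------------------------------------------------
# Monthly summaries (Thom's normal approximation)
# ---------------------------------------------------------------------------

def thom_degree_days(monthly_mean, daily_sd, n_days, threshold) -> np.ndarray | float:
    """Degree days from a monthly mean and daily standard deviation.

    Treats daily temperature within the month as Normal(μ, σ) and returns the
    expected cumulative excess ``n σ [z Φ(z) + φ(z)]`` with ``z = (μ - b)/σ``.
    As σ → 0 this reduces to the hinge ``n max(μ - b, 0)``.
    """
    mu = np.asarray(monthly_mean, dtype=float)
    sd = np.asarray(daily_sd, dtype=float)
    n = np.asarray(n_days, dtype=float)
    b = np.asarray(threshold, dtype=float)
    if np.any(sd < 0):
        raise ValueError("daily_sd must be nonnegative")
    if np.any(n < 1):
        raise ValueError("n_days must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu - b) / np.where(sd > 0, sd, np.inf)
    dd = n * sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z))
    dd = np.where(sd == 0, n * np.maximum(mu - b, 0.0), dd)
    out = np.maximum(dd, 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Seasonal accumulation
# ---------------------------------------------------------------------------

@dataclass
class SeasonWeather:
    """Season-cumulative weather for one unit-year."""

    exposure: ExposureDistribution
    degree_days: dict[float, float]
    prcp_total: float
    tmean: float
    n_days: int


def accumulate_season(
    days: Sequence[DayWeather],
    thresholds: Sequence[float] = (),
    prcp: Sequence[float] | None = None,
    bin_edges=None,
    allow_missing: bool = False,
) -> SeasonWeather:
    """Accumulate per-day exposures over a season window.

    Bin masses and degree days are additive across days; the seasonal mean
    temperature is the mean of the daily midpoints (or hourly means).  Days
    with non-finite extremes raise unless ``allow_missing`` flags them, in
    which case they are skipped and the day count reduced.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    total = ExposureDistribution(bin_edges=np.asarray(bin_edges, dtype=float))
    dd = {float(b): 0.0 for b in thresholds}
    tmeans: list[float] = []
    n_used = 0
    for day in days:
        if not isinstance(day, DayWeather):
            day = DayWeather(*day) if isinstance(day, tuple) else DayWeather(tmin=day, tmax=day)
        if day.hourly is None and not (np.isfinite(day.tmin) and np.isfinite(day.tmax)):
            if allow_missing:
                continue
            raise ValueError("missing (non-finite) day in season window; pass allow_missing=True")
        total = total + day_bin_exposure_sine(day, bin_edges=bin_edges)
        for b in dd:
            if day.hourly is not None:
                dd[b] += degree_days_hourly(day.hourly, b)
            else:
                dd[b] += degree_days_sine(day.tmin, day.tmax, threshold=b)
        tmeans.append(
            float(np.mean(day.hourly)) if day.hourly is not None
            else 0.5 * (day.tmin + day.tmax)
        )
        n_used += 1
    prcp_total = float(np.nansum(prcp)) if prcp is not None else 0.0
    tmean = float(np.mean(tmeans)) if tmeans else float("nan")
    return SeasonWeather(total, dd, prcp_total, tmean, n_used)


# ---------------------------------------------------------------------------
# Station infill
# ---------------------------------------------------------------------------

def quantile_infill(
    target_record,
    neighbor_percentiles,
    neighbor_distances,
    power: float = 1.0,
) -> float:
    """Fill a missing station value by quantile matching against neighbors.

    Computes the inverse-distance-weighted mean of the neighbors' same-day
    percentiles (in [0, 1]) and returns that quantile of the target station's
    own empirical distribution (linear interpolation between order
    statistics).  E.g. if the neighbors average their 70th percentile, the
    filled value is the target's own 70th percentile.
    """
    target = np.asarray(target_record, dtype=float)
    target = target[np.isfinite(target)]
    if target.size == 0:
        raise ValueError("target record is empty")
    p = np.asarray(neighbor_percentiles, dtype=float)
    d = np.asarray(neighbor_distances, dtype=float)
    ok = np.isfinite(p)
    p, d = p[ok], d[ok]
    if p.size == 0:
        raise ValueError("all neighbors missing")
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("percentiles must be in [0, 1]")
    w = d ** (-power)
    pbar = float(np.sum(w * p) / np.sum(w))
    return float(np.quantile(target, pbar, method="linear"))
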