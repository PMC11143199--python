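"""Fixed-effects panel models of log yield on seasonal temperature exposure.

The estimating equation regresses log outcome ``y_it`` for unit *i* in year
*t* on a heat response ``Σ_h g(h+½) φ_it(h)`` built from the season's 1 °C
exposure distribution, plus a quadratic in season-total precipitation and
group-specific quadratic time trends, absorbing unit fixed effects; standard
errors are clustered on a coarser group (states).  Four functional forms for
``g`` are supported:

``piecewise``          degree days between a base and a breakpoint (moderate
                       heat, capped at the breakpoint) and above the
                       breakpoint (extreme heat);
``chebyshev8``         an 8th-order Chebyshev polynomial over the exposure
                       distribution (the constant term is dropped — it is the
                       season length, collinear with the fixed effects);
``bins3``              a separate effect for each 3 °C bin, open-ended at the
                       top, with the bin containing the normalization
                       temperature as the omitted reference;
``monthly_quadratic``  a quadratic in the seasonal mean of monthly mean
                       temperature (the coarse specification that masks daily
                       extremes).

Fitted response functions are reported relative to a normalization
temperature (default 10 °C) since levels are absorbed by the fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import chebyshev as _cheb

from .exposure import ExposureDistribution
from .pipeline import SeasonPanel

__all__ = [
    "CollinearityError",
    "YieldPanel",
    "ModelSpec",
    "ResponseModel",
    "build_regressors_piecewise",
    "piecewise_from_dd",
    "build_regressors_chebyshev",
    "build_regressors_bins",
    "build_regressors_monthly_mean",
    "fit_fixed_effects",
    "clustered_covariance",
    "evaluate_response",
    "day_substitution_effect",
    "SubstitutionEffect",
]

logger = logging.getLogger("heatyield")

FORMS = ("piecewise", "chebyshev8", "bins3", "monthly_quadratic")
_FORM_ALIASES = {"chebychev8": "chebyshev8", "cheb8": "chebyshev8", "bins": "bins3",
                 "monthly": "monthly_quadratic", "baseline": None}


class CollinearityError(ValueError):
    """Raised when regressors are collinear after the within-transformation."""


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------

@dataclass
class YieldPanel:
    """Unit × year outcome panel with precomputed seasonal weather covariates.

    ``df`` holds one row per (unit, year): ``unit``, ``year``, ``log_outcome``,
    ``cluster_group``, ``trend_group``, ``prcp_cm``, ``tmean`` and optionally
    ``country`` / ``station``.  Degree days above each precomputed threshold
    are in ``dd`` (rows aligned with ``df``); 1 °C bin exposures (overflow
    folded into the edge bins) in ``exposure`` when available.
    """

    df: pd.DataFrame
    dd: np.ndarray
    thresholds: np.ndarray
    exposure: np.ndarray | None = None
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.df.duplicated(["unit", "year"]).any():
            raise ValueError("(unit, year) pairs must be unique")
        y = self.df["log_outcome"].to_numpy()
        if not np.all(np.isfinite(y)):
            raise ValueError("log_outcome contains non-finite values")
        if len(self.dd) != len(self.df):
            raise ValueError("dd rows must align with df rows")

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.df["year"].to_numpy())

    def dd_above(self, threshold: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.thresholds, float(threshold)))
        if idx.size == 0:
            raise KeyError(f"threshold {threshold} not precomputed")
        return self.dd[:, idx[0]]

    def subset(self, mask: np.ndarray) -> "YieldPanel":
        return YieldPanel(
            df=self.df.loc[mask].reset_index(drop=True),
            dd=self.dd[mask],
            thresholds=self.thresholds,
            exposure=None if self.exposure is None else self.exposure[mask],
            bin_edges=self.bin_edges,
        )

    @classmethod
    def from_season_panel(
        cls,
        season: SeasonPanel,
        log_outcome: np.ndarray,
        unit_meta: pd.DataFrame,
    ) -> "YieldPanel":
        """Flatten a (year × unit) :class:`SeasonPanel` plus outcomes to long form.

        ``unit_meta`` is indexed by unit id with columns ``cluster_group``,
        ``trend_group`` and optionally ``country``, ``station``.
        """
        m, n = season.n_years, season.n_locations
        if log_outcome.shape != (m, n):
            raise ValueError(f"log_outcome must have shape {(m, n)}")
        years = np.repeat(season.years, n)
        units = np.tile(season.ids, m)
        meta = unit_meta.loc[units].reset_index(drop=True)
        df = pd.DataFrame({
            "unit": units,
            "year": years,
            "log_outcome": log_outcome.ravel(),
            "prcp_cm": season.prcp_cm.ravel(),
            "tmean": season.tmean.ravel(),
        })
        for col in ("cluster_group", "trend_group", "country", "station"):
            if col in meta.columns:
                df[col] = meta[col].to_numpy()
        exposure = None
        if season.exposure is not None:
            exposure = season.exposure.copy()
            exposure[:, :, 0] += season.exp_below
            exposure[:, :, -1] += season.exp_above
            exposure = exposure.reshape(m * n, -1)
        keep = np.isfinite(df["log_outcome"].to_numpy())
        panel = cls(
            df=df.loc[keep].reset_index(drop=True),
            dd=season.dd.reshape(m * n, -1)[keep],
            thresholds=season.thresholds,
            exposure=None if exposure is None else exposure[keep],
            bin_edges=season.bin_edges,
        )
        return panel


# ---------------------------------------------------------------------------
# Regressor builders
# ---------------------------------------------------------------------------

def piecewise_from_dd(dd_above_base, dd_above_breakpoint):
    """Moderate/extreme degree-day pair from exact daily accumulations.

    Moderate heat capped at the breakpoint is the identity
    ``dd(base) - dd(breakpoint)``; extreme heat is ``dd(breakpoint)``.
    """
    dd_b = np.asarray(dd_above_base, dtype=float)
    dd_p = np.asarray(dd_above_breakpoint, dtype=float)
    return dd_b - dd_p, dd_p


def build_regressors_piecewise(exp: ExposureDistribution, base: float, breakpoint: float):
    """Moderate/extreme degree days from the 1 °C bin representation.

    Midpoint rule: bin mass at midpoint ``m`` contributes
    ``min(max(m - base, 0), breakpoint - base)`` moderate and
    ``max(m - breakpoint, 0)`` extreme degree days.  Exact daily degree-day
    accumulations (see :func:`piecewise_from_dd`) are preferred when
    available; the bin path discretizes at 1 °C resolution.
    """
    if base >= breakpoint:
        raise ValueError(f"base ({base}) must be below breakpoint ({breakpoint})")
    t = exp.folded()
    mids = exp.midpoints
    moderate = float(np.sum(t * np.clip(mids - base, 0.0, breakpoint - base)))
    extreme = float(np.sum(t * np.maximum(mids - breakpoint, 0.0)))
    return moderate, extreme


def _cheb_x(temps, domain):
    lo, hi = domain
    if not hi > lo:
        raise ValueError("degenerate Chebyshev domain")
    return 2.0 * (np.asarray(temps, dtype=float) - lo) / (hi - lo) - 1.0


def build_regressors_chebyshev(time_in_bin, bin_edges=None, order: int = 8,
                               domain=(-4.0, 42.0)) -> np.ndarray:
    """Chebyshev regressors ``term_k = Σ_h T_k(x(h+½)) φ(h)`` for k = 1..order.

    ``time_in_bin`` may be an :class:`ExposureDistribution` or an array of
    folded bin masses with the bin axis last; k = 0 is omitted (it equals the
    season length, absorbed by unit fixed effects on balanced panels).
    """
    if isinstance(time_in_bin, ExposureDistribution):
        bin_edges = time_in_bin.bin_edges
        time_in_bin = time_in_bin.folded()
    if bin_edges is None:
        raise TypeError("bin_edges required when time_in_bin is an array")
    t = np.asarray(time_in_bin, dtype=float)
    mids = 0.5 * (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:]))
    V = _cheb.chebvander(_cheb_x(mids, domain), order)[:, 1:]
    return t @ V


def _bin_groups(bin_edges, width, top):
    """Group 1 °C bins into ``width``-degree bins whose top bin opens at ``top``."""
    mids = 0.5 * (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:]))
    rel = np.floor((mids - top) / width).astype(int)  # 0 => open top bin
    rel = np.minimum(rel, 0)
    gmin = rel.min()
    group_of_bin = rel - gmin
    n_groups = -gmin + 1
    lowers = top + width * np.arange(gmin, 1)
    uppers = np.append(lowers[1:], np.inf)
    lowers = lowers.astype(float)
    lowers[0] = -np.inf  # bottom group collects everything below
    return group_of_bin, list(zip(lowers, uppers))


def build_regressors_bins(time_in_bin, bin_edges=None, width: float = 3.0,
                          top: float = 36.0):
    """Day counts per ``width``-degree bin, open-ended at ``top``.

    Returns ``(terms, groups)`` where ``groups`` is a list of (lower, upper)
    edges; the top group is ``[top, inf)``.  Total mass is conserved:
    the wide bins sum to the same day count as the 1 °C bins.
    """
    if isinstance(time_in_bin, ExposureDistribution):
        bin_edges = time_in_bin.bin_edges
        time_in_bin = time_in_bin.folded()
    if bin_edges is None:
        raise TypeError("bin_edges required when time_in_bin is an array")
    t = np.asarray(time_in_bin, dtype=float)
    group_of_bin, groups = _bin_groups(bin_edges, width, top)
    terms = np.zeros(t.shape[:-1] + (len(groups),))
    np.add.at(terms.reshape(-1, len(groups)),
              (slice(None), group_of_bin),
              t.reshape(-1, t.shape[-1]))
    return terms, groups


def build_regressors_monthly_mean(tmean):
    """Quadratic pair (T, T²) in the season mean of monthly mean temperature."""
    T = np.asarray(tmean, dtype=float)
    return np.stack([T, T * T], axis=-1)


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Functional form plus control configuration (frozen at fit time)."""

    form: str | None = "piecewise"
    base: float = 10.0
    breakpoint: float | None = None
    cheb_order: int = 8
    cheb_domain: tuple = (-4.0, 42.0)
    bin_width: float = 3.0
    bin_top: float = 36.0
    norm_temp: float = 10.0
    controls: tuple = ("precip", "trends")
    year_fe: bool = False
    cluster_col: str = "cluster_group"
    trend_col: str = "trend_group"
    # filled in at fit time so held-out designs use identical coding
    year_center: float | None = None
    trend_levels: tuple | None = None
    year_levels: tuple | None = None
    bin_groups: list | None = None
    ref_bin: int | None = None

    def __post_init__(self) -> None:
        self.form = _FORM_ALIASES.get(self.form, self.form)
        if self.form is not None and self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; choose from {FORMS}")
        if self.form == "piecewise":
            if self.breakpoint is None:
                raise ValueError("piecewise form requires a breakpoint")
            if self.base >= self.breakpoint:
                raise ValueError("base must be below breakpoint")


def _heat_design(panel: YieldPanel, spec: ModelSpec):
    """Heat regressor block (N × k_heat) and column names."""
    if spec.form is None:
        return np.empty((panel.n_obs, 0)), []
    if spec.form == "piecewise":
        mod, ext = piecewise_from_dd(panel.dd_above(spec.base),
                                     panel.dd_above(spec.breakpoint))
        return np.column_stack([mod, ext]), ["dd_moderate", "dd_extreme"]
    if spec.form == "monthly_quadratic":
        X = build_regressors_monthly_mean(panel.df["tmean"].to_numpy())
        return X, ["tmean", "tmean_sq"]
    if panel.exposure is None:
        raise ValueError(f"form {spec.form!r} needs the 1 °C exposure distribution")
    if spec.form == "chebyshev8":
        X = build_regressors_chebyshev(panel.exposure, panel.bin_edges,
                                       spec.cheb_order, spec.cheb_domain)
        return X, [f"cheb_{k}" for k in range(1, spec.cheb_order + 1)]
    if spec.form == "bins3":
        terms, groups = build_regressors_bins(panel.exposure, panel.bin_edges,
                                              spec.bin_width, spec.bin_top)
        if spec.bin_groups is None:
            spec.bin_groups = groups
            spec.ref_bin = next(i for i, (lo, hi) in enumerate(groups)
                                if lo <= spec.norm_temp < hi)
        keep = [i for i in range(len(groups)) if i != spec.ref_bin]
        names = [f"bin_{groups[i][0]:g}_{groups[i][1]:g}" for i in keep]
        return terms[:, keep], names
    raise AssertionError(spec.form)


def _control_design(panel: YieldPanel, spec: ModelSpec):
    df = panel.df
    cols, names = [], []
    if "precip" in spec.controls and spec.form is not None:
        p = df["prcp_cm"].to_numpy(dtype=float)
        cols += [p, p * p]
        names += ["prcp", "prcp_sq"]
    year = df["year"].to_numpy(dtype=float)
    if spec.year_center is None:
        spec.year_center = float(year.mean())
    ty = year - spec.year_center
    if "trends" in spec.controls:
        groups = df[spec.trend_col].to_numpy()
        if spec.trend_levels is None:
            spec.trend_levels = tuple(np.unique(groups))
        # with year fixed effects the common trend is absorbed, so one
        # group's trend columns must be dropped for identification
        levels = spec.trend_levels[1:] if spec.year_fe else spec.trend_levels
        for g in levels:
            ind = (groups == g).astype(float)
            cols += [ind * ty, ind * ty * ty]
            names += [f"trend1_{g}", f"trend2_{g}"]
    if spec.year_fe:
        if spec.year_levels is None:
            spec.year_levels = tuple(np.unique(year))
        for yv in spec.year_levels[1:]:  # first year is the reference
            cols.append((year == yv).astype(float))
            names.append(f"year_{int(yv)}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _full_design(panel: YieldPanel, spec: ModelSpec):
    Xh, hn = _heat_design(panel, spec)
    Xc, cn = _control_design(panel, spec)
    return np.hstack([Xh, Xc]), hn + cn, hn


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _segment_sums(v: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Column-wise per-group sums via bincount (much faster than np.add.at)."""
    if v.ndim == 1:
        return np.bincount(codes, weights=v, minlength=n_groups)
    out = np.empty((n_groups, v.shape[1]))
    for j in range(v.shape[1]):
        out[:, j] = np.bincount(codes, weights=v[:, j], minlength=n_groups)
    return out


def clustered_covariance(X: np.ndarray, resid: np.ndarray, clusters,
                         n_absorbed: int = 0) -> np.ndarray:
    """Cluster-robust sandwich covariance for OLS coefficients.

    ``(X'X)^{-1} [Σ_g X_g' e_g e_g' X_g] (X'X)^{-1}`` scaled by the
    small-sample factor ``G/(G-1) · (N-1)/(N-K)`` where ``K`` counts the
    reported coefficients plus ``n_absorbed`` swept-out fixed effects.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(resid, dtype=float)
    codes, uniques = pd.factorize(np.asarray(clusters))
    G = len(uniques)
    if G < 2:
        raise ValueError("clustered covariance requires at least 2 clusters")
    N, k = X.shape
    Xe = X * e[:, None]
    S = _segment_sums(Xe, codes, G)  # per-cluster score sums
    meat = S.T @ S
    bread = np.linalg.pinv(X.T @ X)
    K = k + n_absorbed
    c = (G / (G - 1)) * ((N - 1) / (N - K))
    V = c * bread @ meat @ bread
    return 0.5 * (V + V.T)


@dataclass
class ResponseModel:
    """A fitted fixed-effects response function with clustered uncertainty."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    heat_names: list
    unit_effects: pd.Series
    nobs: int
    n_units: int
    n_clusters: int
    resid_rms: float
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def form(self) -> str | None:
        return self.spec.form

    @property
    def heat_params(self) -> pd.Series:
        return self.params[self.heat_names]

    @property
    def heat_cov(self) -> np.ndarray:
        return self.cov.loc[self.heat_names, self.heat_names].to_numpy()

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    # -- prediction ---------------------------------------------------------

    def predict(self, panel: YieldPanel) -> np.ndarray:
        """Fitted log outcome for each panel row; NaN for units unseen at fit
        time (their fixed effect is unidentified)."""
        X, names, _ = _full_design(panel, self.spec)
        beta = self.params.reindex(names).to_numpy()
        if np.any(~np.isfinite(beta)):
            missing = [n for n in names if n not in self.params.index]
            raise ValueError(f"design produced unknown columns: {missing}")
        alpha = self.unit_effects.reindex(panel.df["unit"]).to_numpy()
        return X @ beta + alpha

    # -- response-curve queries ---------------------------------------------

    def _heat_gradient(self, temps) -> np.ndarray:
        """d g(T)/d heat-coefficients, relative to the normalization point."""
        T = np.atleast_1d(np.asarray(temps, dtype=float))
        s = self.spec
        ref = s.norm_temp
        if s.form == "piecewise":
            cap = s.breakpoint - s.base
            mod = np.clip(T - s.base, 0.0, cap) - np.clip(ref - s.base, 0.0, cap)
            ext = np.maximum(T - s.breakpoint, 0.0) - max(ref - s.breakpoint, 0.0)
            return np.column_stack([mod, ext])
        if s.form == "monthly_quadratic":
            return np.column_stack([T - ref, T * T - ref * ref])
        if s.form == "chebyshev8":
            lo, hi = s.cheb_domain
            if np.any((T < lo) | (T > hi)):
                raise ValueError(f"temperature outside Chebyshev domain {s.cheb_domain}")
            V = _cheb.chebvander(_cheb_x(T, s.cheb_domain), s.cheb_order)[:, 1:]
            V0 = _cheb.chebvander(_cheb_x([ref], s.cheb_domain), s.cheb_order)[:, 1:]
            return V - V0
        if s.form == "bins3":
            if s.bin_groups is None:
                raise ValueError("bins model has no fitted bin layout")
            grad = np.zeros((len(T), len(self.heat_names)))
            keep = [i for i in range(len(s.bin_groups)) if i != s.ref_bin]
            for j, t in enumerate(T):
                g = next(i for i, (lo, hi) in enumerate(s.bin_groups) if lo <= t < hi)
                if g != s.ref_bin:
                    grad[j, keep.index(g)] = 1.0
            return grad
        raise ValueError("baseline model has no response curve")


def fit_fixed_effects(panel: YieldPanel, form: str | None = "piecewise",
                      compute_cov: bool = True, **spec_kwargs) -> ResponseModel:
    """Estimate the response by least squares with unit fixed effects absorbed.

    The within-transformation demeans outcome and regressors by unit, which
    is numerically identical to including a dummy per unit.  Collinear
    regressors (e.g. constant within every unit) raise
    :class:`CollinearityError` naming the offending columns.
    """
    spec = ModelSpec(form=form, **spec_kwargs)
    df = panel.df
    y = df["log_outcome"].to_numpy(dtype=float)
    X, names, heat_names = _full_design(panel, spec)

    codes, unit_levels = pd.factorize(df["unit"])
    n_units = len(unit_levels)
    counts = np.bincount(codes).astype(float)
    if np.any(counts < 2):
        logger.warning("%d unit(s) observed in a single year", int(np.sum(counts < 2)))

    def demean(v):
        means = _segment_sums(v, codes, n_units)
        means /= counts.reshape((-1,) + (1,) * (v.ndim - 1))
        return v - means[codes], means

    Xd, _ = demean(X)
    yd, _ = demean(y)

    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    dead = np.sqrt((Xd ** 2).sum(axis=0)) < 1e-10 * np.sqrt(len(y)) * scale
    if np.any(dead):
        bad = [names[i] for i in np.flatnonzero(dead)]
        raise CollinearityError(
            f"regressors constant within units (absorbed by fixed effects): {bad}")

    k = X.shape[1]
    dof = len(y) - n_units - k
    if dof < 1:
        raise ValueError(f"insufficient degrees of freedom (N={len(y)}, "
                         f"units={n_units}, k={k})")
    beta, _, rank, _ = np.linalg.lstsq(Xd, yd, rcond=None)
    if rank < k:
        raise CollinearityError(
            f"design matrix rank {rank} < {k} after within-transformation "
            f"(columns: {names})")
    resid = yd - Xd @ beta

    if compute_cov:
        clusters = df[spec.cluster_col].to_numpy()
        V = clustered_covariance(Xd, resid, clusters, n_absorbed=n_units)
        n_clusters = len(pd.unique(clusters))
    else:  # prediction-only fits (e.g. inside cross-validation loops)
        V = np.full((k, k), np.nan)
        n_clusters = 0

    # unit effects recovered on the original scale for prediction
    fit_means = _segment_sums(y - X @ beta, codes, n_units)
    alpha = pd.Series(fit_means / counts, index=pd.Index(unit_levels, name="unit"))

    return ResponseModel(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        heat_names=heat_names,
        unit_effects=alpha,
        nobs=len(y),
        n_units=n_units,
        n_clusters=n_clusters,
        resid_rms=float(np.sqrt(np.mean(resid ** 2))),
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Response-curve queries
# ---------------------------------------------------------------------------

def evaluate_response(model: ResponseModel, temperature):
    """Δ log yield at ``temperature`` relative to the normalization point,
    with a delta-method standard error from the clustered covariance."""
    grad = model._heat_gradient(temperature)
    beta = model.heat_params.to_numpy()
    V = model.heat_cov
    val = grad @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", grad, V, grad))
    if np.ndim(temperature) == 0:
        return float(val[0]), float(se[0])
    return val, se


@dataclass
class SubstitutionEffect:
    """Percent yield change from swapping a full day between two temperatures."""

    pct: float
    se_pct: float
    from_temp: float
    to_temp: float
    argmax_temp: float


def day_substitution_effect(model: ResponseModel, to_temp: float,
                            from_temp: float = 10.0,
                            search_range=(0.0, 40.0)) -> SubstitutionEffect:
    """Percent yield change for replacing a full day at ``from_temp`` with a
    full day at ``to_temp``: ``100·[g(to) - g(from)]`` with its standard
    error, plus the yield-maximizing temperature found by a 0.1 °C grid
    search over ``search_range``.  Invariant to the normalization point.
    """
    grad = (model._heat_gradient([to_temp]) - model._heat_gradient([from_temp]))[0]
    beta = model.heat_params.to_numpy()
    V = model.heat_cov
    val = float(grad @ beta)
    se = float(np.sqrt(grad @ V @ grad))
    lo, hi = search_range
    grid = np.arange(lo, hi + 1e-9, 0.1)
    gvals = model._heat_gradient(grid) @ beta
    argmax = float(grid[int(np.argmax(gvals))])
    return SubstitutionEffect(100.0 * val, 100.0 * se, from_temp, to_temp, argmax)
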