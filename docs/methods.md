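# Methods

## Exposure construction

Daily records carry only the extremes (tmin, tmax), so the within-day path
is modelled as a single-period sine `T(t) = M + W sin(2πt)`,
`M = (tmax+tmin)/2`, `W = (tmax−tmin)/2`. Two closed forms follow:

* time above a level `b` (interior case): `(π − 2 asin((b−M)/W)) / 2π`;
* degree days above `b` (interior case):
  `[(M−b)(π/2−θ) + W cos θ]/π` with `θ = asin((b−M)/W)`,
  reducing to `M − b` when the whole day is above and 0 when below.

A constant day (`W = 0`) is handled by a separate branch (counted as above
`b` iff `M ≥ b`), avoiding the degenerate arcsine. Exposure is tabulated on
1 °C half-open bins `[h, h+1)` for `h = −4 … 41` with open overflow bins
outside; bin masses are first differences of the time-above curve at
consecutive integer edges, so each day's masses are nonnegative and sum to
one exactly. The single sine is the default because it keeps days
independent; a double-sine variant (rise to the maximum as one half-period
sine, fall to the *next* day's minimum as another) is provided for users
who want asymmetric days — each monotone half-sine occupies temperatures
exactly as a full sine with the same endpoints does, so the variant is the
equal-weight average of two single-sine closed forms.
Hourly records, when available, are binned directly at 1/24 day per hour,
and the discretization error against the sine forms is below 0.05 degree
days for diurnal amplitudes up to 15 °C (tested).

Monthly summaries cannot resolve days at all; degree days are then
estimated by the Thom normal model: with daily temperature ~ Normal(μ, σ)
within the month, the expected cumulative excess above `b` over `n` days is
`n σ [z Φ(z) + φ(z)]`, `z = (μ−b)/σ`, which tends to the hinge
`n max(μ−b, 0)` as σ → 0.

Gappy station records are infilled by quantile matching: the
inverse-distance-weighted mean (power 1) of the neighbors' same-day
percentiles, evaluated in the target's own empirical distribution with
linear interpolation between order statistics.

## Spatial aggregation

Because the response is nonlinear, bin exposures and degree days are always
computed per grid cell per day and only then averaged to administrative
units. Unit weights are crop share × overlap fraction, row-normalized; the
centroid rule (cell wholly assigned to the unit containing its centroid)
suits fine grids, the overlap rule coarse grids. Crop weights are
time-invariant. Units whose total weight falls below 1e−12 are flagged
cropless and dropped with a warning. Geometry enters only as precomputed
overlap fractions, keeping the module independent of any polygon format.

## Panel estimation

The estimator absorbs unit fixed effects by within-demeaning (numerically
identical to unit dummies, verified against a dummy-variable OLS oracle to
1e−10) and regresses demeaned log outcome on the heat regressors, a
quadratic in season-total precipitation (cm), and group-specific quadratic
time trends centered at the sample mid-year for conditioning. Collinear
columns raise an error naming the offenders rather than silently dropping
them. An optional year-fixed-effects variant drops the first trend group's
columns, since year dummies absorb the common trend component.

Heat functional forms:

* **piecewise** — moderate degree days between a base (default 10 °C, also
  the plot normalization point; configurable) and the breakpoint, capped at
  the breakpoint via the identity `dd(base) − dd(breakpoint)`, plus extreme
  degree days above the breakpoint. Panel fitting uses exact daily
  degree-day accumulations; a 1 °C-bin midpoint-rule path exists for
  exposure-only inputs.
* **chebyshev8** — terms `Σ_h T_k(x(h+½)) φ(h)`, `k = 1…8`, with the bin
  range −4…42 °C mapped linearly to [−1, 1]. The k = 0 term equals the
  season length and is collinear with unit effects on balanced panels, so
  it is omitted.
* **bins3** — day counts per 3 °C bin anchored so the top bin opens at
  36 °C (`[36, ∞)`); the bin containing the normalization temperature is
  the omitted reference.
* **monthly_quadratic** — (T, T²) in the season mean of *monthly mean*
  temperature, deliberately reproducing the information loss of
  monthly-aggregated data.

The clustered covariance is the sandwich
`(X'X)⁻¹ [Σ_g X_g'e_g e_g'X_g] (X'X)⁻¹` scaled by
`G/(G−1) · (N−1)/(N−K)`, with `K` counting the absorbed unit intercepts —
the convention under which it coincides exactly with dummy-variable OLS
clustered errors. Response-curve queries are reported relative to the
normalization temperature with delta-method standard errors; day
substitution effects are invariant to that normalization (tested), and the
yield-maximizing temperature is found by a 0.1 °C grid search.

## Cross-validation and model selection

Yield shocks are spatially correlated within a year, so held-out sets are
sampled by year: each repetition trains on `ceil(f·Y)` years (f = 0.85 by
default; 0.75 for the short vegetation-index panels, scored on the
remaining 25%) and predicts the rest, using training-sample fixed effects
and trend coefficients — the standard choice; units unseen in training are
dropped from evaluation. Skill is `100·(1 − RMS_model/RMS_baseline)`
against a no-weather baseline of fixed effects plus trends (precipitation
counts as weather and is excluded from the baseline). Breakpoint selection
scores every candidate (default grid 20…36 °C, 1 °C steps) on the same
splits — a common-random-numbers design that removes split noise from the
comparison — and maximizes mean reduction, ties going to the lower
threshold; selection optimizes RMS reduction, which ranks identically to
raw RMS given the shared baseline. Reduction distributions are compared by
Welch's unequal-variance t test with Satterthwaite degrees of freedom.

The station-stratified design for data-sparse regions fixes the set of
cells containing weather stations and, per repetition, draws as many
station-free cells per country as that country has stations, so the
country composition of both sets matches even when stations are
concentrated in a couple of countries; piecewise bounds are taken as given,
not re-selected, and models use cell fixed effects with country trends.

## Warming scenarios

Uniform warming adds Δ °C to every temperature reading, leaves
precipitation, trends and fixed effects at baseline, rebuilds exposures at
cell level, and aggregates with the original weights. Per-unit Δlog-yield
is the change in heat regressors dotted with the heat coefficients;
aggregation uses equal unit weights by default (crop-area or production
weights can be supplied). The headline number is
`100·(exp(mean Δlog) − 1)` — the percent-change convention implied by a
log-yield model — with a linearized `100·Δlog` option. Intervals are 2.5/
97.5 percentiles over multivariate-normal coefficient draws from the
clustered covariance; the point estimate uses the mean coefficients, so
Δ = 0 yields exactly 0 ± 0.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any
particular region's climate:

* **Weather.** Daily mean temperature = seasonal cosine (annual mean 12 °C,
  amplitude 14 °C, peak day 200) + anomalies with sd 4 °C, AR(1)
  persistence 0.7 across days (restarting each season), and spatial
  correlation from Gaussian-kernel smoothing of white noise (length scale
  2 cells). The diurnal range is gamma-distributed with mean 10 °C (shape
  10), split evenly around the daily mean, so tmax ≥ tmin by construction.
  Daily precipitation is gamma (shape 0.5, scale 5 mm), independent across
  cells and days. These values produce midsummer maxima in the low-to-mid
  30s °C — enough mass above candidate breakpoints for the threshold to be
  identifiable, as in real row-crop regions.
* **Landscape.** Contiguous rectangular "counties" tile the grid and nest
  into "states" (trend and cluster groups) and "countries"; crop shares are
  Beta(2, 2); station flags place 70% of stations in 2 designated host
  countries by default, mimicking the concentration of station networks.
* **Outcomes.** Log yield = unit effect (sd 0.3) + state quadratic trend +
  quadratic precipitation + piecewise heat response (breakpoint 29 °C,
  slopes +0.0004 and −0.006 per degree day — synthetic, order-of-magnitude
  plausible for row crops, not estimates) + Gaussian noise of sd 0.2 log
  points, so weather explains a minority share of the year-to-year
  variance, as in field data. With zero noise, outcomes lie exactly in the
  span of the true regressors, giving exact-recovery oracles. A cell-level
  variant with country groupings and station flags stands in for the
  vegetation-index panels of data-sparse regions.

What the generator does **not** emulate: reanalysis measurement-error
structure, satellite retrieval physics, irrigation, adaptation, spatially
correlated yield shocks beyond what weather induces, or heterogeneous
responses across countries. Passing tests therefore demonstrate that the
estimators recover the truth under the model's own assumptions, not that
those assumptions hold in any particular data set.

## Problem sizes and numerical choices

Simulation studies use sizes chosen to make their Monte-Carlo checks
well-powered at desk scale: slope recovery and CI coverage on 200 panels
of 500 units × 30 years; breakpoint recovery on 150 units × 30 years with
16 CV repetitions per candidate over 50 seeds per truth; functional-form
ordering on 80 units × 25 years with 30 repetitions over 20 seeds.
Seeds fix all randomness end to end (weather, landscape, outcomes, CV
splits, coefficient draws), with independent substreams per stage so
generating one component never perturbs another. Conservation identities
(bin masses summing to the day count) hold to 1e−12 per day; closed forms
are tested against brute-force integration of the sine path at 1e−4
days/1e−3 degree days. Arcsine arguments are clipped to [−1, 1] against
floating-point overshoot.

## Known limitations

* The piecewise "moderate" segment starts at a configurable base (10 °C);
  exposures below it are treated as neutral rather than harmful (no cold
  penalty).
* The bins form cannot represent within-bin slopes; its open top bin
  assigns one effect to all heat above 36 °C.
* Thom's formula assumes within-month normality and a known daily sd.
* Cross-validation predictions require units to appear in training; on
  short panels with heavy missingness the evaluable held-out set shrinks.
* NetCDF output uses the NETCDF3_CLASSIC format (scipy backend).
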