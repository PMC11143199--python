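"""Degree days and within-day exposure from daily temperature extremes.

The closed forms interpolate each day with a sine wave between tmin and
tmax, so a partial-day excursion above a threshold is counted by how long
and how far it exceeds it.
"""

import numpy as np

import heatyield as hy

# Worked examples at a 30 degC threshold: a constant 32 degC day contributes
# 2 degree days, a 28 degC day none, and two 31 degC days together 2.
print("constant 32 degC day :", hy.degree_days_sine(32, 32, threshold=30), "dd")
print("constant 28 degC day :", hy.degree_days_sine(28, 28, threshold=30), "dd")
season = hy.accumulate_season([hy.DayWeather(tmin=31, tmax=31)] * 2,
                              thresholds=[30.0])
print("two 31 degC days     :", season.degree_days[30.0], "dd")

# A day swinging 20..40 degC spends exactly 1/3 of its time above 35 degC
# and accumulates 10/pi degree days above 30 degC.
print("fraction above 35    :", hy.fraction_above_sine(20, 40, 35))
print("dd above 30 (20..40) :", hy.degree_days_sine(20, 40, threshold=30),
      "=", 10 / np.pi)

# From monthly summaries (mean 28, daily sd 2, 30 days) the Thom normal
# approximation estimates the expected cumulative excess above 30 degC.
print("Thom dd (mu=28,sd=2) :", round(hy.thom_degree_days(28, 2, 30, 30), 3))

# Station infill by quantile matching: neighbors at their 70th percentile
# imply the target's own 70th percentile.
record = np.random.default_rng(0).normal(15, 5, 365)
filled = hy.quantile_infill(record, np.full(10, 0.7), np.ones(10))
print("infilled value       :", round(filled, 3),
      "(= target's own 70th pct:", round(np.quantile(record, 0.7), 3), ")")
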