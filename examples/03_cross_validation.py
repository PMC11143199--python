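"""Compare functional forms by out-of-sample skill.

Each model is repeatedly fit on a random 85% of years and scored on the
held-out 15%; skill is the percent reduction in held-out RMS relative to a
no-weather baseline (county fixed effects + state quadratic trends).  Forms
that use daily temperature extremes beat the quadratic in the seasonal
average, which averages away the damaging hot days.
"""

import heatyield as hy

config = hy.SyntheticConfig(n_cells_x=10, n_cells_y=8, n_units=80,
                            years=range(1995, 2020), n_states=8, seed=2)
weather = hy.generate_weather_grid(config)
landscape = hy.generate_landscape(config)
panel = hy.generate_outcome_panel(weather, landscape, hy.TrueResponse(),
                                  config, thresholds=[10.0, 29.0],
                                  compute_bins=True)

cv = hy.CVConfig(n_reps=100, train_fraction_years=0.85, seed=0)
print("form                 mean    median   IQR of RMS reduction (%)")
for form, kwargs in [("piecewise", {"breakpoint": 29.0}),
                     ("chebyshev8", {}),
                     ("bins3", {}),
                     ("monthly_quadratic", {})]:
    res = hy.cv_rms_reduction(panel, form, cv, **kwargs)
    s = res.summary()
    print(f"{form:20s} {s['mean']:6.2f} {s['median']:8.2f}"
          f"   [{s['q25']:.2f}, {s['q75']:.2f}]")
print("\nHigher is better; 0 means weather explains none of the "
      "year-to-year variation, 100 all of it.")
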