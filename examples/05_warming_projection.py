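"""Project yield losses under uniform warming.

Every temperature reading in the baseline climate is raised by a constant
1-4 degC, exposures are rebuilt at the grid-cell level, and the change in
heat regressors is pushed through the fitted response.  Intervals come from
1000 draws of the coefficients using their clustered covariance.
"""

import heatyield as hy

config = hy.SyntheticConfig(n_cells_x=10, n_cells_y=6, n_units=60,
                            years=range(2000, 2020), n_states=6, seed=1)
weather = hy.generate_weather_grid(config)
landscape = hy.generate_landscape(config)
panel = hy.generate_outcome_panel(weather, landscape, hy.TrueResponse(),
                                  config, thresholds=[10.0, 29.0])
model = hy.fit_fixed_effects(panel, "piecewise", breakpoint=29.0)

impacts = hy.project_impacts(model, weather, landscape.weights("centroid"),
                             deltas=[1, 2, 3, 4], n_draws=1000, seed=0)
print("warming   aggregate yield change   95% interval")
for imp in impacts:
    print(f"  +{imp.delta:.0f} degC   {imp.point_pct:8.1f}%"
          f"            [{imp.lo_pct:.1f}%, {imp.hi_pct:.1f}%]")
print("\nLosses steepen with warming: each extra degree converts more "
      "moderate exposure into damaging extreme degree days.")
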