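"""Regressor construction, the within-estimator, clustered uncertainty, and
response-curve queries, checked against hand arithmetic and a dummy-variable
OLS oracle (statsmodels)."""

import numpy as np
import pandas as pd
import pytest

import heatyield as hy
from heatyield.exposure import ExposureDistribution, default_bin_edges
from heatyield.response import ModelSpec, ResponseModel


def make_model(form="piecewise", params=None, cov=None, **spec_kwargs):
    """A ResponseModel with hand-set coefficients (no fitting)."""
    if form == "piecewise":
        spec_kwargs.setdefault("breakpoint", 29.0)
        names = ["dd_moderate", "dd_extreme"]
        params = params if params is not None else [4e-4, -6e-3]
    elif form == "monthly_quadratic":
        names = ["tmean", "tmean_sq"]
    else:
        raise ValueError(form)
    spec = ModelSpec(form=form, **spec_kwargs)
    cov = np.zeros((len(names), len(names))) if cov is None else np.asarray(cov)
    return ResponseModel(
        spec=spec, params=pd.Series(params, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names), heat_names=names,
        unit_effects=pd.Series(dtype=float), nobs=0, n_units=0, n_clusters=0,
        resid_rms=0.0)


def point_mass_exposure(temp, days=1.0):
    edges = default_bin_edges()
    t = np.zeros(len(edges) - 1)
    t[np.searchsorted(edges, temp, side="right") - 1] = days
    return ExposureDistribution(bin_edges=edges, time_in_bin=t)


class TestPiecewiseRegressors:
    def test_exact_daily_path_worked_examples(self):
        # constant 32 °C day, base 10, breakpoint 30
        mod, ext = hy.piecewise_from_dd(
            hy.degree_days_sine(32, 32, threshold=10),
            hy.degree_days_sine(32, 32, threshold=30))
        assert (mod, ext) == (20.0, 2.0)
        # constant 5 °C day contributes nothing above base 10
        mod, ext = hy.piecewise_from_dd(
            hy.degree_days_sine(5, 5, threshold=10),
            hy.degree_days_sine(5, 5, threshold=30))
        assert (mod, ext) == (0.0, 0.0)
        # constant 20 °C day: 10 moderate degree days, no extreme
        mod, ext = hy.piecewise_from_dd(
            hy.degree_days_sine(20, 20, threshold=10),
            hy.degree_days_sine(20, 20, threshold=30))
        assert (mod, ext) == (10.0, 0.0)

    def test_bin_midpoint_path(self):
        # mass at midpoint 20.5 -> moderate 10.5 under the 1 °C midpoint rule
        mod, ext = hy.build_regressors_piecewise(point_mass_exposure(20.0), 10.0, 30.0)
        assert (mod, ext) == (10.5, 0.0)
        mod, ext = hy.build_regressors_piecewise(point_mass_exposure(32.0), 10.0, 30.0)
        assert (mod, ext) == (20.0, 2.5)

    def test_base_must_precede_breakpoint(self):
        with pytest.raises(ValueError):
            hy.build_regressors_piecewise(point_mass_exposure(20.0), 30.0, 30.0)


class TestChebyshevRegressors:
    def test_zero_exposure_gives_zero_terms(self):
        exp = ExposureDistribution()
        assert hy.build_regressors_chebyshev(exp) == pytest.approx(np.zeros(8))

    def test_point_mass_evaluates_basis_at_midpoint(self):
        exp = point_mass_exposure(25.0, days=3.0)
        x = 2 * (25.5 - (-4)) / 46 - 1
        # Chebyshev recurrence oracle
        T = [1.0, x]
        for k in range(2, 9):
            T.append(2 * x * T[-1] - T[-2])
        assert hy.build_regressors_chebyshev(exp) == pytest.approx(
            3.0 * np.array(T[1:]))

    def test_two_bin_exposure_matches_brute_force(self):
        edges = default_bin_edges()
        t = np.zeros(len(edges) - 1)
        t[10], t[30] = 2.0, 5.0
        exp = ExposureDistribution(bin_edges=edges, time_in_bin=t)
        mids = exp.midpoints
        brute = np.zeros(8)
        for m, d in [(mids[10], 2.0), (mids[30], 5.0)]:
            x = 2 * (m - (-4)) / 46 - 1
            T = [1.0, x]
            for k in range(2, 9):
                T.append(2 * x * T[-1] - T[-2])
            brute += d * np.array(T[1:])
        assert hy.build_regressors_chebyshev(exp) == pytest.approx(brute)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            hy.build_regressors_chebyshev(point_mass_exposure(20.0), domain=(5, 5))


class TestBinRegressors:
    def test_constant_day_lands_in_its_bin(self):
        terms, groups = hy.build_regressors_bins(point_mass_exposure(20.0))
        idx = next(i for i, (lo, hi) in enumerate(groups) if lo <= 20 < hi)
        assert terms[idx] == 1.0
        assert terms.sum() == 1.0

    def test_hot_day_in_open_top_bin(self):
        terms, groups = hy.build_regressors_bins(point_mass_exposure(40.0))
        assert groups[-1][1] == np.inf and groups[-1][0] == 36.0
        assert terms[-1] == 1.0

    def test_mass_conservation_across_widths(self, noisy_panel):
        terms, _ = hy.build_regressors_bins(noisy_panel.exposure,
                                            noisy_panel.bin_edges)
        assert terms.sum(axis=-1) == pytest.approx(noisy_panel.exposure.sum(axis=-1))


class TestMonthlyRegressors:
    @pytest.mark.parametrize("T,expected", [(20.0, (20.0, 400.0)), (0.0, (0.0, 0.0))])
    def test_quadratic_pair(self, T, expected):
        assert hy.build_regressors_monthly_mean(T) == pytest.approx(expected)


class TestFixedEffectsFit:
    def test_zero_noise_panel_recovers_truth_exactly(self, quiet_panel):
        truth = hy.TrueResponse()
        m = hy.fit_fixed_effects(quiet_panel, "piecewise", breakpoint=29.0)
        assert m.params["dd_moderate"] == pytest.approx(truth.slope_moderate, abs=1e-8)
        assert m.params["dd_extreme"] == pytest.approx(truth.slope_extreme, abs=1e-8)
        assert m.params["prcp"] == pytest.approx(truth.precip_lin, abs=1e-8)
        assert m.params["prcp_sq"] == pytest.approx(truth.precip_quad, abs=1e-8)

    def test_two_unit_toy_matches_dummy_variable_ols(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "unit": [0, 0, 0, 1, 1, 1],
            "year": [2000, 2001, 2002] * 2,
            "cluster_group": [0, 0, 0, 1, 1, 1],
            "trend_group": [0] * 6,
            "prcp_cm": rng.gamma(5, 8, 6),
            "tmean": rng.normal(20, 3, 6),
            "log_outcome": rng.normal(0, 1, 6),
        })
        panel = hy.YieldPanel(df=df, dd=np.zeros((6, 1)), thresholds=np.array([10.0]))
        m = hy.fit_fixed_effects(panel, "monthly_quadratic", controls=())
        import statsmodels.formula.api as smf
        oracle = smf.ols("log_outcome ~ tmean + I(tmean**2) + C(unit)", df).fit()
        assert m.params["tmean"] == pytest.approx(oracle.params["tmean"], abs=1e-8)
        assert m.params["tmean_sq"] == pytest.approx(
            oracle.params["I(tmean ** 2)"], abs=1e-8)

    def test_full_model_matches_statsmodels_clustered_oracle(self):
        rng = np.random.default_rng(0)
        n_u, n_t = 12, 8
        df = pd.DataFrame({
            "unit": np.repeat(np.arange(n_u), n_t),
            "year": np.tile(np.arange(2000, 2000 + n_t), n_u),
        })
        df["cluster_group"] = df["unit"] % 4
        df["trend_group"] = df["unit"] % 2
        df["prcp_cm"] = rng.gamma(5, 8, len(df))
        df["tmean"] = rng.normal(20, 3, len(df))
        dd10 = rng.gamma(9, 150, len(df))
        dd29 = dd10 * rng.uniform(0.01, 0.08, len(df))
        df["log_outcome"] = (rng.normal(0, 0.5, len(df))
                             + 4e-4 * (dd10 - dd29) - 6e-3 * dd29)
        panel = hy.YieldPanel(df=df, dd=np.column_stack([dd10, dd29]),
                              thresholds=np.array([10.0, 29.0]))
        m = hy.fit_fixed_effects(panel, "piecewise", breakpoint=29.0)

        d = df.copy()
        d["mod"] = dd10 - dd29
        d["ext"] = dd29
        d["ty"] = d["year"] - d["year"].mean()
        import statsmodels.formula.api as smf
        oracle = smf.ols(
            "log_outcome ~ mod + ext + prcp_cm + I(prcp_cm**2)"
            " + C(trend_group):ty + C(trend_group):I(ty**2) + C(unit)",
            data=d).fit(cov_type="cluster", cov_kwds={"groups": d["cluster_group"]})
        assert m.params["dd_moderate"] == pytest.approx(oracle.params["mod"], abs=1e-10)
        assert m.params["dd_extreme"] == pytest.approx(oracle.params["ext"], abs=1e-10)
        assert m.bse()["dd_moderate"] == pytest.approx(oracle.bse["mod"], rel=1e-8)
        assert m.bse()["dd_extreme"] == pytest.approx(oracle.bse["ext"], rel=1e-8)

    def test_regressor_constant_within_unit_raises(self):
        df = pd.DataFrame({
            "unit": [0, 0, 1, 1, 2, 2],
            "year": [2000, 2001] * 3,
            "cluster_group": [0, 0, 0, 1, 1, 1],
            "trend_group": [0] * 6,
            "prcp_cm": [5.0, 5.0, 7.0, 7.0, 3.0, 3.0],  # no within variation
            "tmean": np.arange(6, dtype=float),
            "log_outcome": np.arange(6, dtype=float) * 0.1,
        })
        panel = hy.YieldPanel(df=df, dd=np.zeros((6, 1)), thresholds=np.array([10.0]))
        with pytest.raises(hy.CollinearityError, match="prcp"):
            hy.fit_fixed_effects(panel, "monthly_quadratic", controls=("precip",))

    def test_year_fixed_effects_variant(self, quiet_panel):
        truth = hy.TrueResponse()
        m = hy.fit_fixed_effects(quiet_panel, "piecewise", breakpoint=29.0,
                                 year_fe=True)
        assert m.params["dd_extreme"] == pytest.approx(truth.slope_extreme, abs=1e-8)

    def test_insufficient_degrees_of_freedom(self):
        df = pd.DataFrame({
            "unit": [0, 0, 1, 1], "year": [2000, 2001] * 2,
            "cluster_group": [0, 0, 1, 1], "trend_group": [0] * 4,
            "prcp_cm": [1.0, 2.0, 3.0, 4.0], "tmean": [1.0, 2.0, 3.0, 4.0],
            "log_outcome": [0.1, 0.2, 0.3, 0.4],
        })
        panel = hy.YieldPanel(df=df, dd=np.zeros((4, 1)), thresholds=np.array([10.0]))
        with pytest.raises(ValueError, match="degrees of freedom"):
            hy.fit_fixed_effects(panel, "monthly_quadratic", controls=("precip",))


class TestClusteredCovariance:
    def test_zero_residuals_give_zero_matrix(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        V = hy.clustered_covariance(X, np.zeros(10), np.repeat([0, 1], 5))
        assert V == pytest.approx(np.zeros((2, 2)))

    def test_each_observation_own_cluster_reduces_to_hc1(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        e = rng.normal(size=40)
        V = hy.clustered_covariance(X, e, np.arange(40))
        bread = np.linalg.inv(X.T @ X)
        meat = (X * e[:, None] ** 2 * 1).T @ X  # sum x_i x_i' e_i^2
        meat = (X * (e ** 2)[:, None]).T @ X
        hc1 = 40 / (40 - 3) * bread @ meat @ bread
        # factor G/(G-1)*(N-1)/(N-K) = N/(N-K) when every cluster is singleton
        assert V == pytest.approx(hc1, rel=1e-10)

    def test_two_cluster_toy_matches_hand_assembly(self):
        X = np.array([[1.0, 0.5], [1.0, -1.0], [2.0, 0.0], [0.5, 1.5]])
        e = np.array([0.3, -0.2, 0.1, 0.4])
        cl = np.array([0, 0, 1, 1])
        s0 = X[:2].T @ e[:2]
        s1 = X[2:].T @ e[2:]
        meat = np.outer(s0, s0) + np.outer(s1, s1)
        bread = np.linalg.inv(X.T @ X)
        c = (2 / 1) * (3 / 2)  # G/(G-1) * (N-1)/(N-K), K = 2
        expected = c * bread @ meat @ bread
        assert hy.clustered_covariance(X, e, cl) == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            hy.clustered_covariance(np.ones((4, 1)), np.ones(4), np.zeros(4))

    def test_symmetric_psd(self, noisy_panel):
        m = hy.fit_fixed_effects(noisy_panel, "piecewise", breakpoint=29.0)
        V = m.cov.to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-15


class TestResponseCurve:
    def test_normalization_point_is_zero(self):
        model = make_model()
        val, se = hy.evaluate_response(model, 10.0)
        assert val == 0.0 and se == 0.0

    def test_piecewise_closed_form_at_36(self):
        model = make_model()  # slopes 4e-4 / -6e-3, breakpoint 29, base 10
        val, _ = hy.evaluate_response(model, 36.0)
        assert val == pytest.approx(19 * 4e-4 + 7 * -6e-3)

    def test_bins_constant_within_bin(self, noisy_panel):
        m = hy.fit_fixed_effects(noisy_panel, "bins3")
        v1, _ = hy.evaluate_response(m, 18.5)
        v2, _ = hy.evaluate_response(m, 20.9)  # same [18, 21) bin
        assert v1 == v2

    def test_chebyshev_out_of_domain(self, noisy_panel):
        m = hy.fit_fixed_effects(noisy_panel, "chebyshev8")
        with pytest.raises(ValueError):
            hy.evaluate_response(m, 60.0)

    def test_flexible_forms_track_true_response_on_clean_data(self, quiet_panel):
        # misspecified-but-flexible fits stay within 3x their own residual
        # scale of the true piecewise curve over the cropping range
        truth = hy.TrueResponse()
        grid = np.arange(10.0, 36.01, 0.5)
        g_true = (truth.slope_moderate * np.clip(grid - 10, 0, 19)
                  + truth.slope_extreme * np.maximum(grid - 29, 0))
        for form in ("chebyshev8", "bins3"):
            m = hy.fit_fixed_effects(quiet_panel, form)
            vals, _ = hy.evaluate_response(m, grid)
            assert np.abs(vals - g_true).max() < 3 * m.resid_rms


class TestDaySubstitution:
    def test_same_temperature_is_zero(self):
        eff = hy.day_substitution_effect(make_model(), to_temp=10.0)
        assert eff.pct == 0.0

    def test_closed_form_substitution_to_36(self):
        eff = hy.day_substitution_effect(make_model(), to_temp=36.0)
        assert eff.pct == pytest.approx(100 * (7 * -6e-3 + 19 * 4e-4))

    def test_argmax_is_breakpoint_for_opposite_slopes(self):
        eff = hy.day_substitution_effect(make_model(), to_temp=36.0)
        assert eff.argmax_temp == pytest.approx(29.0)

    def test_invariant_to_normalization_temperature(self, noisy_panel):
        m1 = hy.fit_fixed_effects(noisy_panel, "piecewise", breakpoint=29.0,
                                  norm_temp=10.0)
        m2 = hy.fit_fixed_effects(noisy_panel, "piecewise", breakpoint=29.0,
                                  norm_temp=20.0)
        e1 = hy.day_substitution_effect(m1, to_temp=36.0)
        e2 = hy.day_substitution_effect(m2, to_temp=36.0)
        assert e1.pct == pytest.approx(e2.pct, abs=1e-12)
        assert e1.se_pct == pytest.approx(e2.se_pct, abs=1e-12)
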