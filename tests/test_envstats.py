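"""Environmental preparation and growth-environment statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coralchron import synthgen
from coralchron.envstats import (EnvSeries, annual_climate, annualize,
                                 fit_trend, growth_env_analysis, pearson,
                                 rescale_series)


def _monthly(values, start="2000-01-01"):
    idx = pd.date_range(start, periods=len(values), freq="MS")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def _annual(values, first_year=1950):
    return pd.Series(np.asarray(values, dtype=float),
                     index=np.arange(first_year, first_year + len(values)))


class TestAnnualize:
    def test_constant_year_mean_min_max_coincide(self):
        s = _monthly([28.0] * 12)
        assert annualize(s, "mean").loc[2000] == 28.0
        assert annualize(s, "min").loc[2000] == 28.0
        assert annualize(s, "max").loc[2000] == 28.0

    def test_sinusoid_extrema_exact(self):
        # 27 + 2 cos peaked in September: max 29, min 25, at machine precision
        s = synthgen.gen_env_monthly("sst", 2005, 2007, 27.0, seasonal_amp=2.0,
                                     peak_month=9)
        clim = annual_climate(s)
        assert np.allclose(clim["max"].to_numpy(), 29.0)
        assert np.allclose(clim["min"].to_numpy(), 25.0)
        assert np.all(clim["min"] <= clim["mean"])
        assert np.all(clim["mean"] <= clim["max"])

    def test_years_with_many_gaps_dropped_and_reported(self):
        s = _monthly(np.arange(36.0))
        s = s.drop(s.index[[2, 5, 8]])  # 2000 loses three months
        out = annualize(s, "mean")
        assert 2000 not in out.index
        assert out.attrs["dropped_years"] == [2000]
        assert {2001, 2002} <= set(out.index)

    def test_monthly_overlap_count_for_shared_span(self):
        # two complete series over 2012-2020 share 9 * 12 = 108 months
        a = synthgen.gen_env_monthly("precipitation", 2012, 2020, 150.0,
                                     seasonal_amp=50.0, noise_sd=10.0, seed=1)
        b = synthgen.gen_env_monthly("discharge", 2012, 2020, 2.0,
                                     seasonal_amp=1.0, noise_sd=0.5, seed=2)
        joined = pd.concat([a, b], axis=1, join="inner").dropna()
        assert len(joined) == 108

    def test_annual_statistic_requires_known_name(self):
        with pytest.raises(ValueError, match="statistic"):
            annualize(_monthly([1.0] * 12), "median")


class TestRescale:
    def test_identity_when_target_equals_reference(self):
        idx = pd.date_range("1932-01-01", "2018-12-01", freq="MS")
        ref = pd.Series(100 + 20 * np.sin(np.arange(len(idx)) / 6.0), index=idx)
        target = ref[ref.index.year >= 1993]
        res = rescale_series(target, ref, (1993, 2018), n_mc=50, seed=0)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        pre = ref[ref.index.year < 1993]
        assert np.allclose(res.rescaled.to_numpy(), pre.to_numpy(), atol=1e-8)
        width = (res.envelope["hi"] - res.envelope["lo"]).max()
        assert width == pytest.approx(0.0, abs=1e-6)

    def test_known_line_recovered_within_2_se(self):
        # truth a=5, b=0.8, residual sd 10 mm, 300 overlap months, seed 9
        rng = np.random.default_rng(9)
        idx = pd.date_range("1932-01-01", periods=740, freq="MS")
        ref = pd.Series(rng.uniform(50, 250, len(idx)), index=idx)
        overlap_start = idx[-300].year
        noisy = 5.0 + 0.8 * ref + rng.normal(0, 10.0, len(idx))
        target = noisy[noisy.index >= idx[-300]]
        res = rescale_series(target, ref, (overlap_start, idx[-1].year),
                             n_mc=200, seed=9)
        se_b = 10.0 / (np.std(ref.iloc[-300:]) * np.sqrt(300))
        assert abs(res.slope - 0.8) < 2 * se_b
        assert res.n_overlap >= 299

    def test_envelope_coverage_of_true_values(self):
        # 95% parameter-uncertainty envelope covers the true (noise-free)
        # mapped values in 93-97% of pre-overlap months, across 50 seeds
        cov = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            idx = pd.date_range("1932-01-01", "1993-12-01", freq="MS")
            ref = pd.Series(100 + 30 * np.sin(np.arange(len(idx)) / 6.0)
                            + rng.normal(0, 15, len(idx)), index=idx)
            truth_full = 5.0 + 0.8 * ref
            noisy = truth_full + rng.normal(0, 10.0, len(idx))
            target = noisy[noisy.index.year >= 1969]
            res = rescale_series(target, ref, (1969, 1993), n_mc=300, seed=seed)
            truth_pre = truth_full[truth_full.index < target.index.min()]
            inside = ((truth_pre >= res.envelope["lo"])
                      & (truth_pre <= res.envelope["hi"]))
            cov.append(inside.mean())
        assert 0.93 <= np.mean(cov) <= 0.97

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        idx = pd.date_range("1960-01-01", periods=400, freq="MS")
        ref = pd.Series(rng.uniform(0, 100, len(idx)), index=idx)
        target = (3.0 + 1.2 * ref + rng.normal(0, 5, len(idx)))[idx.year >= 1980]
        a = rescale_series(target, ref, (1980, 1993), n_mc=100, seed=7)
        b = rescale_series(target, ref, (1980, 1993), n_mc=100, seed=7)
        pd.testing.assert_frame_equal(a.envelope, b.envelope)

    def test_insufficient_overlap_rejected(self):
        idx = pd.date_range("2000-01-01", periods=36, freq="MS")
        ref = pd.Series(np.arange(36.0), index=idx)
        target = ref[ref.index.year >= 2002]
        with pytest.raises(ValueError, match="24"):
            rescale_series(target, ref, (2002, 2002), n_mc=10, seed=0)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson([1, 2, 3], [-2, -4, -6]).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        res = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)
        assert res.n == 4

    def test_zero_variance_flagged_not_nan_propagated(self):
        res = pearson([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
        assert not res.valid
        assert "zero variance" in res.note

    def test_year_alignment_is_inner_join(self):
        x = _annual(np.arange(10.0), 1950)
        y = _annual(np.arange(8.0) * 2, 1955)
        res = pearson(x, y)
        assert res.n == 5  # 1955-1959
        assert res.r == pytest.approx(1.0)

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        base = pearson(x, y).r
        scaled = pearson(a * x + b, y).r
        assert scaled == pytest.approx(base, abs=1e-9)
        flipped = pearson(-a * x + b, y).r
        assert flipped == pytest.approx(-base, abs=1e-9)


class TestFitTrend:
    def test_exact_line(self):
        res = fit_trend([0, 1, 2], [1, 3, 5], degree=1)
        assert res.coefficients == pytest.approx([2.0, 1.0])
        assert res.r2 == pytest.approx(1.0)

    def test_exact_parabola(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        res = fit_trend(x, x**2, degree=2)
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients[0] == pytest.approx(1.0)

    def test_noisy_slope_within_3_se(self):
        # oracle: closed-form OLS standard error
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 100)
        y = 2.0 * x + rng.normal(0, 0.1, 100)
        res = fit_trend(x, y, degree=1)
        se = 0.1 / (np.std(x) * np.sqrt(100))
        assert abs(res.coefficients[0] - 2.0) < 3 * se
        assert res.p < 1e-6

    def test_log_y_fits_exponential_as_line(self):
        x = np.arange(1.0, 21.0)
        y = np.exp(0.3 * x + 1.0)
        res = fit_trend(x, y, degree=1, log_y=True)
        assert res.coefficients == pytest.approx([0.3, 1.0], abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_trend([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0], degree=1)


class TestGrowthEnvAnalysis:
    def test_exact_linear_dependence_gives_r2_one_everywhere(self):
        pop = _annual(np.linspace(200, 400, 71), 1950)
        growth = np.exp(-0.002 * pop)  # log(growth) exactly linear in pop
        masters = {"extension": pd.Series(growth.to_numpy(), index=pop.index)}
        table = growth_env_analysis(masters, {"population": pop},
                                    periods=[(1950, 1985), (1986, 2020)])
        lin = table[table.model == "linear"]
        assert np.allclose(lin["r2"].to_numpy(), 1.0)
        assert set(lin["period"]) == {"full", "1950-1985", "1986-2020"}

    def test_split_period_contrast(self):
        # negative dependence only before the split year: significant
        # negative fit in period 1, none in period 2
        rng = np.random.default_rng(8)
        years = np.arange(1950, 2021)
        pop = _annual(np.linspace(200, 400, years.size), 1950)
        log_g = np.where(years <= 1985, -0.004 * pop.to_numpy(), -0.004 * 290)
        growth = pd.Series(np.exp(log_g + rng.normal(0, 0.02, years.size)),
                           index=years)
        table = growth_env_analysis({"calcification": growth},
                                    {"population": pop},
                                    periods=[(1950, 1985), (1986, 2020)])
        p1 = table[(table.period == "1950-1985") & (table.model == "pearson")]
        p2 = table[(table.period == "1986-2020") & (table.model == "pearson")]
        assert p1["r"].iloc[0] < 0 and p1["p"].iloc[0] < 0.05
        assert p2["p"].iloc[0] > 0.05

    def test_parabolic_response_prefers_degree_two(self):
        # density peaks at an interior optimum: quadratic beats linear
        sst = _annual(np.linspace(27.5, 30.5, 71), 1950)
        dens = 2.0 - 0.05 * (sst.to_numpy() - 29.0) ** 2
        masters = {"density": pd.Series(dens, index=sst.index)}
        table = growth_env_analysis(masters, {"sst_max": sst}, periods=[])
        full = table[table.period == "full"]
        r2_lin = full[full.model == "linear"]["r2"].iloc[0]
        r2_quad = full[full.model == "poly2"]["r2"].iloc[0]
        assert r2_quad > r2_lin
        # log-transform of an exact parabola is only near-quadratic
        assert r2_quad > 0.99

    def test_bh_adjustment_column_optional_and_monotone(self):
        rng = np.random.default_rng(6)
        g = pd.Series(np.exp(rng.normal(-0.8, 0.05, 71)),
                      index=np.arange(1950, 2021))
        env = {"a": _annual(rng.normal(0, 1, 71), 1950),
               "b": _annual(rng.normal(0, 1, 71), 1950)}
        plain = growth_env_analysis({"extension": g}, env, periods=[])
        adj = growth_env_analysis({"extension": g}, env, periods=[],
                                  adjust_p=True)
        assert "p_adj" not in plain.columns
        mask = adj["p"].notna()
        assert np.all(adj.loc[mask, "p_adj"] >= adj.loc[mask, "p"] - 1e-12)

    def test_insufficient_overlap_marked(self):
        g = pd.Series([0.4, 0.41, 0.42], index=[2000, 2001, 2002])
        e = _annual([1.0, 2.0, 3.0], 1950)
        table = growth_env_analysis({"extension": g}, {"x": e}, periods=[])
        assert (table["note"] == "insufficient overlap").all()


def test_env_series_csv_round_trip(tmp_path):
    s = synthgen.gen_env_monthly("sst", 2000, 2001, 28.0, 1.0, seed=0)
    s.rename("value").rename_axis("date").to_csv(tmp_path / "sst.csv")
    back = EnvSeries.from_csv(tmp_path / "sst.csv", units="degC", kind="sst")
    assert isinstance(back.data.index, pd.DatetimeIndex)
    assert np.allclose(back.data.to_numpy(), s.to_numpy())
    with pytest.raises(ValueError, match="units"):
        EnvSeries(data=s, units="")
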