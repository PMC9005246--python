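"""Attributable fractions: closed forms, oracles and eCI behaviour."""

import numpy as np
import pandas as pd
import pytest

from heatlag import attribution as att
from heatlag import dlnm_stage1 as d1
from heatlag.spline_bases import bspline_basis, natural_cubic_basis


def make_manual_fit(daily, theta_b, theta_i=None, time_varying=True, var_spec=None):
    """DLNMFit with prescribed cross-basis coefficients (no model fitting)."""
    cb = d1.build_crossbasis(daily, var_spec=var_spec)
    k = cb.n_var * cb.n_lag
    blocks = {"intercept": np.array([0]), "crossbasis": np.arange(1, 1 + k)}
    coef = [0.0, *theta_b]
    if time_varying:
        blocks["interaction"] = np.arange(1 + k, 1 + 2 * k)
        coef += list(theta_i if theta_i is not None else np.zeros(k))
    coef = np.asarray(coef, dtype=float)
    dates = cb.dates
    p10, p90 = np.percentile(cb.tmean, [10, 90])
    return d1.DLNMFit(
        coef=coef,
        vcov=np.zeros((len(coef), len(coef))),
        dispersion=1.0,
        blocks=blocks,
        date_center=dates.min() + (dates.max() - dates.min()) / 2,
        date_span_days=float(max((dates.max() - dates.min()).days, 1)),
        n_obs=len(dates),
        deviance=0.0,
        crossbasis=cb,
        temp_percentiles=(float(p10), float(p90)),
    )


def toy_daily(n=40, year=2005, seed=0, lo=5, hi=30):
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{year}-05-01", periods=n, freq="D")
    return pd.DataFrame({"date": dates, "tmean": rng.uniform(lo, hi, n)})


class TestDailyAF:
    def test_history_at_reference_gives_zero(self):
        daily = toy_daily(30)
        daily["tmean"] = 17.0
        rng = np.random.default_rng(1)
        spec = d1.BasisSpec(kind="bspline", degree=2, interior_knots=(15.0, 22.0),
                            boundary=(5.0, 30.0), intercept=False)
        fit = make_manual_fit(daily, rng.standard_normal(16), var_spec=spec)
        eng = att.AttributionEngine(fit)
        tb, ti = eng.theta_point()
        afs = eng.daily_afs(tb, ti, np.full(1, 17.0))
        np.testing.assert_allclose(afs, 0.0, atol=1e-12)

    def test_closed_form_for_known_cumulative_rr(self):
        # scale coefficients so the cumulative log-RR of the constant history
        # relative to the reference is exactly log(1.1)
        daily = toy_daily(30)  # varying start gives the engine grid its span
        daily.loc[19:, "tmean"] = 25.0  # last 11 days constant: known history
        spec = d1.BasisSpec(kind="bspline", degree=2, interior_knots=(15.0, 22.0),
                            boundary=(5.0, 30.0), intercept=False)
        rng = np.random.default_rng(2)
        theta = rng.standard_normal(16)
        fit = make_manual_fit(daily, theta, var_spec=spec)
        eng = att.AttributionEngine(fit)
        mmt = eng.grid[np.argmin(np.abs(eng.grid - 18.0))]
        cb = fit.crossbasis
        contrast = np.kron(
            cb.var_basis(np.array([25.0])) - cb.var_basis(np.array([mmt])),
            cb.lag_sum[None, :],
        )[0]
        theta = theta * (np.log(1.1) / (contrast @ theta))
        fit = make_manual_fit(daily, theta, var_spec=spec)
        eng = att.AttributionEngine(fit)
        tb, ti = eng.theta_point()
        afs = eng.daily_afs(tb, ti, np.array([mmt]))
        assert afs[-1] == pytest.approx(1 - 1 / 1.1, rel=1e-6)

    def test_matches_direct_evaluation_oracle(self):
        daily = toy_daily(20, seed=3)
        rng = np.random.default_rng(4)
        tb = rng.standard_normal(16) * 0.02
        ti = rng.standard_normal(16) * 0.01
        fit = make_manual_fit(daily, tb, ti)
        eng = att.AttributionEngine(fit)
        mmt = eng.grid[len(eng.grid) // 2]
        afs = eng.daily_afs(*eng.theta_point(), np.array([mmt]))

        cb = fit.crossbasis
        tm = daily["tmean"].to_numpy()
        lags = np.arange(11)
        for t in (0, 5, 12, 19):
            s = fit.date_scale(pd.Timestamp(daily["date"].iloc[t]))
            theta = (tb + s * ti).reshape(cb.n_var, cb.n_lag)
            cum = 0.0
            for l in lags:
                tl = tm[max(t - l, 0)]
                bv = bspline_basis(np.array([tl]), cb.var_spec).values[0]
                bv_ref = bspline_basis(np.array([mmt]), cb.var_spec).values[0]
                bl = natural_cubic_basis(np.array([float(l)]), cb.lag_spec).values[0]
                cum += (bv - bv_ref) @ theta @ bl
            assert afs[t] == pytest.approx(1 - np.exp(-cum), abs=1e-10)

    def test_af_never_exceeds_one(self):
        daily = toy_daily(60, seed=5)
        rng = np.random.default_rng(6)
        fit = make_manual_fit(daily, rng.standard_normal(16) * 2)
        eng = att.AttributionEngine(fit)
        afs = eng.daily_afs(*eng.theta_point(), np.array([eng.grid[0]]))
        assert np.all(afs <= 1.0)


class TestAnnualAF:
    def test_single_heat_day_arithmetic(self):
        dates = pd.date_range("2005-05-01", periods=100, freq="D")
        afs = pd.Series(0.0, index=dates)
        afs.iloc[50] = 0.1
        tmean = np.full(100, 15.0)
        tmean[50] = 30.0
        deaths = np.full(100, 10.0)
        hd = att.HeatDefinition("p95", {2005: 25.0})
        res = att.annual_af(afs, deaths, hd, tmean, 2005)
        assert res["af"] == pytest.approx(0.1 * 10 / 1000)
        assert res["n_heat_days"] == 1

    def test_no_heat_days_gives_zero(self):
        dates = pd.date_range("2005-05-01", periods=50, freq="D")
        afs = pd.Series(0.2, index=dates)
        hd = att.HeatDefinition("p99", {2005: 99.0})
        res = att.annual_af(afs, np.ones(50), hd, np.full(50, 20.0), 2005)
        assert res["af"] == 0.0 and res["n_heat_days"] == 0

    def test_zero_total_deaths_rejected(self):
        dates = pd.date_range("2005-05-01", periods=50, freq="D")
        afs = pd.Series(0.0, index=dates)
        hd = att.HeatDefinition("p95", {2005: 20.0})
        with pytest.raises(ValueError):
            att.annual_af(afs, np.zeros(50), hd, np.full(50, 25.0), 2005)

    def test_attributable_number_is_additive_over_years(self, small_fit):
        fit, daily = small_fit
        _, af_df = att.attribution_table(fit, daily["deaths"].to_numpy())
        mmt_rows = af_df[af_df["heat_def"] == "MMT"]
        years = pd.DatetimeIndex(daily["date"]).year
        afs = att.daily_af(fit)
        hd_all = dict(zip(mmt_rows["year"], [None] * len(mmt_rows)))
        total_an = mmt_rows["an"].sum()
        # recompute AN over the union of all years directly
        eng = att.AttributionEngine(fit)
        tb, ti = eng.theta_point()
        mmts = eng.mmts(tb, ti)
        heat = eng.tmean > mmts[eng.year_pos]
        direct = np.sum(np.where(heat, eng.daily_afs(tb, ti, mmts) * daily["deaths"].to_numpy(), 0.0))
        assert total_an == pytest.approx(direct, rel=1e-12)

    def test_strict_threshold_exceedance(self):
        dates = pd.date_range("2005-05-01", periods=10, freq="D")
        afs = pd.Series(0.5, index=dates)
        tmean = np.full(10, 25.0)  # exactly at threshold: not a heat day
        hd = att.HeatDefinition("p95", {2005: 25.0})
        res = att.annual_af(afs, np.ones(10), hd, tmean, 2005)
        assert res["n_heat_days"] == 0


class TestEmpiricalCI:
    def test_degenerate_vcov_collapses_to_point_estimate(self, small_fit):
        fit, daily = small_fit
        import dataclasses

        degenerate = dataclasses.replace(fit, vcov=np.zeros_like(fit.vcov))
        mmt_df, af_df, period_df = att.empirical_ci(
            degenerate, daily["deaths"].to_numpy(), n_sim=150, seed=0
        )
        np.testing.assert_allclose(mmt_df["eci_lo"], mmt_df["mmt"])
        np.testing.assert_allclose(mmt_df["eci_hi"], mmt_df["mmt"])
        np.testing.assert_allclose(af_df["eci_lo"], af_df["af"], atol=1e-12)
        np.testing.assert_allclose(af_df["eci_hi"], af_df["af"], atol=1e-12)

    def test_fixed_seed_reproducible(self, small_fit):
        fit, daily = small_fit
        a = att.empirical_ci(fit, daily["deaths"].to_numpy(), n_sim=150, seed=7)
        b = att.empirical_ci(fit, daily["deaths"].to_numpy(), n_sim=150, seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_small_n_sim_warns(self, small_fit):
        fit, daily = small_fit
        with pytest.warns(UserWarning, match="n_sim"):
            att.empirical_ci(fit, daily["deaths"].to_numpy(), n_sim=50, seed=1)

    def test_bounds_bracket_point_estimate(self, small_fit):
        fit, daily = small_fit
        _, af_df, period_df = att.empirical_ci(
            fit, daily["deaths"].to_numpy(), n_sim=400, seed=3
        )
        mmt_rows = af_df[af_df["heat_def"] == "MMT"]
        inside = (
            (mmt_rows["eci_lo"] <= mmt_rows["af"]) & (mmt_rows["af"] <= mmt_rows["eci_hi"])
        ).mean()
        assert inside > 0.8
        assert (period_df["eci_lo"] < period_df["eci_hi"]).all()


class TestMonotonicity:
    def test_af_decreases_with_percentile_when_thresholds_exceed_mmt(self, small_fit):
        fit, daily = small_fit
        mmt_df, af_df = att.attribution_table(fit, daily["deaths"].to_numpy())
        wide = af_df.pivot(index="year", columns="heat_def", values="af")
        thr = {
            lab: np.percentile(daily["tmean"], q)
            for lab, q in att.PERCENTILE_LABELS.items()
        }
        for year, row in wide.iterrows():
            mmt = float(mmt_df.loc[mmt_df["year"] == year, "mmt"].iloc[0])
            if min(thr.values()) > mmt:
                assert row["p99"] <= row["p97.5"] + 1e-12
                assert row["p97.5"] <= row["p95"] + 1e-12
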