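"""Cross-basis and quasi-Poisson DLNM against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from heatlag import dlnm_stage1 as d1
from heatlag import synthetic_data as sd
from heatlag.spline_bases import BasisSpec, bspline_basis, natural_cubic_basis


def toy_series(n_days=30, year=2005, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{year}-05-01", periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "tmean": rng.uniform(5, 30, n_days)})


def crossbasis_brute_force(daily, cb):
    """Double-loop direct evaluation of every cross-basis entry."""
    tm = daily["tmean"].to_numpy(dtype=float)
    years = pd.DatetimeIndex(daily["date"]).year.to_numpy()
    n = len(tm)
    v, p = cb.n_var, cb.n_lag
    out = np.zeros((n, v * p))
    for t in range(n):
        for l in range(cb.max_lag + 1):
            # constant extrapolation at season starts
            s = t
            while s - 1 >= 0 and years[s - 1] == years[t] and t - (s - 1) <= l:
                s -= 1
            tl = tm[max(t - l, s)]
            bv = bspline_basis(np.array([tl]), cb.var_spec).values[0]
            bl = natural_cubic_basis(np.array([float(l)]), cb.lag_spec).values[0]
            for i in range(v):
                for j in range(p):
                    out[t, i * p + j] += bv[i] * bl[j]
    return out


class TestCrossBasis:
    def test_matches_double_loop_oracle(self):
        daily = toy_series(30)
        cb = d1.build_crossbasis(daily)
        np.testing.assert_allclose(cb.matrix, crossbasis_brute_force(daily, cb), atol=1e-10)

    def test_oracle_across_season_boundary(self):
        a = toy_series(20, year=2005, seed=1)
        b = toy_series(20, year=2006, seed=2)
        daily = pd.concat([a, b], ignore_index=True)
        cb = d1.build_crossbasis(daily)
        np.testing.assert_allclose(cb.matrix, crossbasis_brute_force(daily, cb), atol=1e-10)

    def test_constant_series_gives_identical_rows(self):
        daily = toy_series(25)
        daily["tmean"] = 17.0
        var_spec = BasisSpec(kind="bspline", degree=2, interior_knots=(15.0, 20.0),
                             boundary=(10.0, 30.0), intercept=False)
        cb = d1.build_crossbasis(daily, var_spec=var_spec)
        np.testing.assert_allclose(cb.matrix, cb.matrix[0][None, :].repeat(25, 0))

    def test_column_count_is_product_of_basis_dims(self):
        daily = toy_series(40)
        var_spec = BasisSpec(kind="bspline", degree=2, interior_knots=(12.0, 18.0, 24.0),
                             boundary=(5.0, 30.0), intercept=True)  # v = 6
        cb = d1.build_crossbasis(daily, var_spec=var_spec)
        assert cb.matrix.shape[1] == 6 * 4
        assert cb.n_var == 6 and cb.n_lag == 4

    def test_incomplete_history_rows_flagged(self):
        daily = toy_series(30)
        cb = d1.build_crossbasis(daily)
        assert cb.incomplete_history[:10].all()
        assert not cb.incomplete_history[10:].any()

    def test_short_season_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            d1.build_crossbasis(toy_series(8))

    def test_duplicate_dates_rejected(self):
        daily = toy_series(15)
        daily.loc[7, "date"] = daily.loc[6, "date"]
        daily = daily.sort_values("date").reset_index(drop=True)
        with pytest.raises(ValueError, match="duplicate"):
            d1.build_crossbasis(daily)


def irls_oracle(X, y, maxiter=60):
    """Hand-written IRLS for log-link Poisson (independent of statsmodels)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-9))
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        WX = X * mu[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestFit:
    def test_coefficients_match_independent_irls(self, small_area):
        daily, _, _ = small_area
        sub = daily[pd.DatetimeIndex(daily["date"]).year <= 2002].reset_index(drop=True)
        cb = d1.build_crossbasis(sub)
        fit = d1.fit_dlnm(cb, sub["deaths"].to_numpy())
        X, _, _, _ = d1._design(cb, 1)
        beta = irls_oracle(X, sub["deaths"].to_numpy(dtype=float))
        np.testing.assert_allclose(fit.coef, beta, rtol=1e-6)

    def test_dispersion_near_one_for_poisson_counts(self):
        disps = []
        for s in range(5):
            zero = lambda t, l: np.zeros_like(np.asarray(t, dtype=float))
            truth = sd.SyntheticTruth(rr_surface=zero, active_index=None,
                                      overdispersion=1.0, seed=100 + s)
            panel = sd.simulate_indices(range(2000, 2012), active=None, seed=100 + s)
            temps = sd.simulate_temperature(panel, truth)
            daily = sd.simulate_mortality(temps, truth)
            cb = d1.build_crossbasis(daily)
            fit = d1.fit_dlnm(cb, daily["deaths"].to_numpy())
            disps.append(fit.dispersion)
        assert abs(np.mean(disps) - 1.0) < 0.1

    def test_overdispersion_estimated(self, small_fit):
        fit, _ = small_fit
        # generator default is 1.2
        assert 1.05 < fit.dispersion < 1.4

    def test_null_crossbasis_wald_not_systematically_significant(self):
        from scipy import stats
        pvals = []
        for s in range(10):
            zero = lambda t, l: np.zeros_like(np.asarray(t, dtype=float))
            truth = sd.SyntheticTruth(rr_surface=zero, active_index=None,
                                      overdispersion=1.0, seed=200 + s)
            panel = sd.simulate_indices(range(2000, 2012), active=None, seed=200 + s)
            temps = sd.simulate_temperature(panel, truth)
            daily = sd.simulate_mortality(temps, truth)
            cb = d1.build_crossbasis(daily)
            fit = d1.fit_dlnm(cb, daily["deaths"].to_numpy())
            idx = fit.blocks["crossbasis"]
            c = fit.coef[idx]
            V = fit.vcov[np.ix_(idx, idx)]
            w = float(c @ np.linalg.solve(V, c))
            pvals.append(1 - stats.chi2.cdf(w, df=len(idx)))
        pvals = np.array(pvals)
        # under the null, p-values are roughly uniform: not concentrated low
        assert (pvals < 0.05).mean() <= 0.3
        assert pvals.mean() > 0.2

    def test_negative_deaths_rejected(self, small_area):
        daily, _, _ = small_area
        cb = d1.build_crossbasis(daily)
        bad = daily["deaths"].to_numpy().copy()
        bad[0] = -1
        with pytest.raises(ValueError):
            d1.fit_dlnm(cb, bad)

    def test_rank_deficient_design_names_block(self):
        daily = toy_series(120)
        daily["tmean"] = 15.0  # constant temperature: collinear cross-basis
        var_spec = BasisSpec(kind="bspline", degree=2, interior_knots=(14.0, 16.0),
                             boundary=(10.0, 20.0), intercept=False)
        cb = d1.build_crossbasis(daily, var_spec=var_spec)
        with pytest.raises(ValueError, match="collinear"):
            d1.fit_dlnm(cb, np.full(120, 50))


class TestExposureResponse:
    def test_interaction_vanishes_at_centering_date(self, small_fit):
        fit, _ = small_fit
        grid = np.linspace(8, 28, 50)
        at_center = d1.cumulative_curve(fit, fit.date_center, grid)
        base_theta = fit.coef[fit.blocks["crossbasis"]].reshape(
            fit.crossbasis.n_var, fit.crossbasis.n_lag
        )
        base_only = fit.crossbasis.var_basis(grid) @ base_theta @ fit.crossbasis.lag_sum
        np.testing.assert_allclose(at_center, base_only, atol=1e-12)

    def test_curve_zero_at_reference(self, small_fit):
        fit, _ = small_fit
        er = d1.predict_exposure_response(fit, pd.Timestamp(2005, 7, 1))
        i = np.argmin(np.abs(er.temp_grid - er.mmt))
        assert er.cum_log_rr[i] == 0.0
        assert er.mmt_bounds[0] <= er.mmt <= er.mmt_bounds[1]

    def test_cumulative_equals_sum_of_lag_specific_curves(self, small_fit):
        fit, _ = small_fit
        cb = fit.crossbasis
        grid = np.linspace(10, 28, 30)
        at = pd.Timestamp(2007, 7, 1)
        theta = fit.effective_cb_coef(at).reshape(cb.n_var, cb.n_lag)
        by_lag = sum(
            cb.var_basis(grid) @ theta @ cb.lag_basis_values[l]
            for l in range(cb.max_lag + 1)
        )
        np.testing.assert_allclose(d1.cumulative_curve(fit, at, grid), by_lag, rtol=1e-10)

    def test_time_constant_fit_equals_base_block_prediction(self, small_area):
        daily, _, _ = small_area
        cb = d1.build_crossbasis(daily)
        fit_tc = d1.fit_dlnm(cb, daily["deaths"].to_numpy(), time_varying=False)
        assert "interaction" not in fit_tc.blocks
        grid = np.linspace(10, 28, 40)
        c1 = d1.cumulative_curve(fit_tc, pd.Timestamp(2001, 7, 1), grid)
        c2 = d1.cumulative_curve(fit_tc, pd.Timestamp(2011, 7, 1), grid)
        np.testing.assert_allclose(c1, c2, atol=1e-12)

    def test_time_varying_fit_agrees_with_time_constant_on_stationary_truth(
        self, small_area
    ):
        daily, _, _ = small_area
        cb = d1.build_crossbasis(daily)
        tv = d1.fit_dlnm(cb, daily["deaths"].to_numpy())
        tc = d1.fit_dlnm(cb, daily["deaths"].to_numpy(), time_varying=False)
        grid = np.linspace(12, 26, 40)
        mid = tc.date_center
        diff = d1.cumulative_curve(tv, mid, grid) - d1.cumulative_curve(tc, mid, grid)
        diff -= diff.mean()
        assert np.max(np.abs(diff)) < 0.05


class TestFindMMT:
    def test_interior_minimum(self):
        grid = np.arange(10.0, 25.01, 0.1)
        curve = (grid - 17.0) ** 2
        assert d1.find_mmt(grid, curve, (12.0, 22.0)) == pytest.approx(17.0)

    def test_monotone_decreasing_returns_upper_bound(self):
        grid = np.arange(10.0, 25.01, 0.1)
        curve = -grid
        assert d1.find_mmt(grid, curve, (12.0, 22.0)) == pytest.approx(22.0)

    def test_flat_curve_warns_and_returns_lower_bound(self):
        grid = np.round(np.arange(10.0, 25.01, 0.1), 10)
        with pytest.warns(UserWarning, match="flat"):
            mmt = d1.find_mmt(grid, np.ones_like(grid), (12.0, 22.0))
        assert mmt == pytest.approx(12.0)

    def test_tie_broken_toward_lower_temperature(self):
        grid = np.arange(10.0, 20.01, 0.1)
        curve = np.abs(grid - 15.0).round(4)  # symmetric around 15
        curve[np.isclose(grid, 14.0)] = 0.0
        curve[np.isclose(grid, 16.0)] = 0.0
        assert d1.find_mmt(grid, curve, (11.0, 19.0)) == pytest.approx(14.0)
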