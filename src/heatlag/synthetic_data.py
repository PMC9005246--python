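"""Synthetic daily temperature/mortality series and monthly climate indices.

Real analyses of this kind rely on mortality registries and gridded weather
products that cannot be redistributed, so the package ships a generator with
known ground truth: a nonlinear lagged exposure-response surface driving
overdispersed daily death counts, a seasonal temperature process whose summer
level is modulated by one "active" low-frequency climate index, and a panel
of monthly index series of which a configurable subset carries true signal.
Every quantity the two modelling stages estimate (the cumulative
exposure-response curve, the minimum-mortality temperature, annual
attributable fractions, the functional index coefficient) has a closed-form
or forward-simulated truth available for testing.

Dates are restricted to the five warmest months, May through September; a
short pre-season burn-in of temperature is generated internally so that
exposure histories are defined from the first season day onward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "SyntheticTruth",
    "TemperatureParams",
    "MortalityParams",
    "default_truth",
    "hockey_stick_surface",
    "half_cosine_beta",
    "simulate_indices",
    "simulate_temperature",
    "simulate_mortality",
    "simulate_area",
    "truth_implied_af",
    "simulate_af_from_indices",
    "write_daily_series",
    "write_index_panel",
    "write_truth",
]

#: Default climate-index labels (Atlantic Multidecadal Oscillation, Southern
#: Oscillation Index, Arctic Oscillation, North Atlantic Oscillation, Oceanic
#: Niño Index, Pacific Decadal Oscillation, Pacific North American pattern).
INDEX_NAMES = ("AMO", "SOI", "AO", "NAO", "ONI", "PDO", "PNA")

MAX_LAG_DAYS = 10
SEASON_START = (5, 1)  # May 1
SEASON_END = (9, 30)  # September 30


# ---------------------------------------------------------------------------
# ground truth


def _smooth_ramp(u: np.ndarray, slope: float, width: float) -> np.ndarray:
    """C1 hinge: quadratic over [0, width], linear with ``slope`` beyond."""
    u = np.clip(u, 0.0, None)
    return np.where(
        u <= width, slope * u**2 / (2 * width), slope * (u - width / 2)
    )


def hockey_stick_surface(
    mmt: float = 18.0,
    heat_slope: float = 0.03,
    cold_slope: float = 0.012,
    heat_ramp: float = 4.0,
    cold_ramp: float = 4.0,
    lag_decay: float = 0.7,
    max_lag: int = MAX_LAG_DAYS,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Piecewise-smooth hockey-stick exposure-lag-response surface (log RR).

    The cumulative (lag-summed) log-RR is flat at ``mmt`` and rises toward a
    linear asymptote of ``heat_slope`` per degree above it, through a
    quadratic ramp of width ``heat_ramp`` degrees (C1 join); a gentler ramp
    of the same form rises below ``mmt``.  The smooth quadratic join keeps
    the surface inside the function class of low-order spline regression —
    the point of a parameter-recovery simulation — and the gentle cold arm
    makes the risk minimum identifiable (a perfectly flat curve below the
    minimum would leave the argmin undefined); mildly U-shaped curves are
    also what temperature-mortality studies observe.  Risk is distributed
    over lags with geometric weights ``lag_decay**l`` normalised to sum to
    one, so the surface cumulates to the stated ramps.
    """
    w = lag_decay ** np.arange(max_lag + 1)
    w = w / w.sum()

    def surface(temp: np.ndarray, lag: np.ndarray) -> np.ndarray:
        temp = np.asarray(temp, dtype=float)
        lagw = w[np.asarray(lag, dtype=int)]
        excess = _smooth_ramp(temp - mmt, heat_slope, heat_ramp) + _smooth_ramp(
            mmt - temp, cold_slope, cold_ramp
        )
        return excess * lagw

    return surface


def half_cosine_beta(amplitude: float = 0.01, span: int = 5) -> Callable[[np.ndarray], np.ndarray]:
    """Functional index coefficient: half cosine over monthly lags 0..span."""

    def beta(lag: np.ndarray) -> np.ndarray:
        lag = np.asarray(lag, dtype=float)
        return np.where(lag <= span, amplitude * np.cos(np.pi * lag / (2 * span)), 0.0)

    return beta


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic area.

    ``rr_surface(temp, lag)`` returns the log relative risk contributed by a
    day with mean temperature ``temp`` at lag ``lag`` (days); it cumulates to
    zero over lags at ``mmt_true``.  ``beta_true(lag_months)`` is the
    functional coefficient linking monthly values of the active climate index
    to the annual heat-attributable fraction; it is identically zero when no
    index is active.
    """

    rr_surface: Callable[[np.ndarray, np.ndarray], np.ndarray]
    mmt_true: float = 18.0
    active_index: str | None = "AMO"
    beta_true: Callable[[np.ndarray], np.ndarray] | None = None
    overdispersion: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1 (Poisson limit)")
        if self.active_index is None and self.beta_true is not None:
            raise ValueError("beta_true must be None/zero when no index is active")
        if self.beta_true is None:
            self.beta_true = (lambda lag: np.zeros_like(np.asarray(lag, dtype=float)))
        lags = np.arange(MAX_LAG_DAYS + 1)
        cum = float(np.sum(self.rr_surface(np.full_like(lags, self.mmt_true, dtype=float), lags)))
        if abs(cum) > 1e-8:
            raise ValueError("rr_surface must cumulate to 0 at mmt_true")


def default_truth(seed: int = 0, active_index: str | None = "AMO") -> SyntheticTruth:
    """Study-condition defaults: V-shaped surface with MMT 18 °C and a
    truth-implied annual AF above the MMT of roughly 2-3 %."""
    beta = half_cosine_beta() if active_index is not None else None
    return SyntheticTruth(
        rr_surface=hockey_stick_surface(),
        mmt_true=18.0,
        active_index=active_index,
        beta_true=beta,
        overdispersion=1.2,
        seed=seed,
    )


@dataclass(frozen=True)
class TemperatureParams:
    """Daily temperature process: sinusoidal seasonal cycle plus AR(1) noise
    plus a summer shift proportional to the active index's January-May mean."""

    base: float = 8.0  # °C annual-cycle level
    amplitude: float = 12.0  # °C annual-cycle amplitude
    peak_doy: int = 200  # day of year of the warmest day (mid July)
    ar_rho: float = 0.7  # day-to-day noise autocorrelation
    ar_sd: float = 3.5  # marginal SD of the daily noise (°C)
    gamma: float = 1.5  # °C shift per SD of the active index
    burn_in_days: int = 10


@dataclass(frozen=True)
class MortalityParams:
    """Baseline mean model for daily all-cause deaths (log scale)."""

    baseline: float = 60.0  # mean daily deaths of a large metropolitan area
    trend: float = -0.10  # total log-linear change across the study period
    season_amp: float = 0.05  # log amplitude of within-season seasonality
    weekday_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.02, -0.03)

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if len(self.weekday_effects) != 7:
            raise ValueError("need 7 weekday effects (Mon..Sun)")


# ---------------------------------------------------------------------------
# generators


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(key + 1)[key])


def simulate_indices(
    years: Sequence[int],
    n_indices: int = 7,
    active: str | None = "AMO",
    seed: int = 0,
    rho_active: float = 0.9,
    rho_other: float = 0.3,
    index_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Monthly climate-index panel with stationary AR(1) columns.

    The panel covers January of (first year - 1) through December of the last
    year so that the 16-month stage-2 lag window is always complete.  Each
    index is an independent AR(1) series — slowly varying (lag-1
    autocorrelation ``rho_active``, default 0.9) for the active index,
    faster (``rho_other``) otherwise — standardised to zero mean and unit
    variance.
    """
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    if n_indices < 1:
        raise ValueError("n_indices must be >= 1")
    names = list(index_names) if index_names is not None else list(INDEX_NAMES[:n_indices])
    if len(names) != n_indices:
        raise ValueError("index_names length must equal n_indices")
    if active is not None and active not in names:
        raise ValueError(f"active index {active!r} not among {names}")

    rng = _spawn(seed, 0)
    first, last = min(years) - 1, max(years)
    n_months = 12 * (last - first + 1)
    cols = {}
    for name in names:
        rho = rho_active if name == active else rho_other
        x = np.empty(n_months)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n_months - 1) * np.sqrt(1.0 - rho**2)
        for t in range(1, n_months):
            x[t] = rho * x[t - 1] + innov[t - 1]
        cols[name] = (x - x.mean()) / x.std()
    month_idx = np.arange(n_months)
    panel = pd.DataFrame(
        {"year": first + month_idx // 12, "month": month_idx % 12 + 1, **cols}
    )
    panel.attrs["index_names"] = names
    panel.attrs["active_index"] = active
    return panel


def _season_dates(year: int, burn_in_days: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(year, *SEASON_START) - pd.Timedelta(days=burn_in_days)
    return pd.date_range(start, pd.Timestamp(year, *SEASON_END), freq="D")


def _index_jan_may_mean(panel: pd.DataFrame, name: str, year: int) -> float:
    sel = (panel["year"] == year) & (panel["month"] <= 5)
    if sel.sum() < 5:
        raise ValueError(f"panel does not cover Jan-May {year}")
    return float(panel.loc[sel, name].mean())


def simulate_temperature(
    panel: pd.DataFrame,
    truth: SyntheticTruth,
    params: TemperatureParams = TemperatureParams(),
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Daily mean temperature for the May-September season of each year.

    tmean = seasonal sinusoid + AR(1) daily noise + gamma * (January-May mean
    of the active index of that year), the last term applied uniformly to all
    days of the year's block.  A ``burn_in_days``-day pre-season stretch is
    generated (rows flagged ``in_season == False``) so that the mortality
    simulator has complete lag histories on May 1.
    """
    if years is None:
        years = sorted(panel.loc[panel["month"] == 12, "year"].unique())[1:]
    years = list(years)
    rng = _spawn(truth.seed, 1)
    frames = []
    for year in years:
        dates = _season_dates(year, params.burn_in_days)
        doy = dates.dayofyear.to_numpy(dtype=float)
        seasonal = params.base + params.amplitude * np.cos(
            2 * np.pi * (doy - params.peak_doy) / 365.25
        )
        n = len(dates)
        noise = np.empty(n)
        noise[0] = rng.standard_normal() * params.ar_sd
        innov = rng.standard_normal(n - 1) * params.ar_sd * np.sqrt(1 - params.ar_rho**2)
        for t in range(1, n):
            noise[t] = params.ar_rho * noise[t - 1] + innov[t - 1]
        shift = 0.0
        if truth.active_index is not None and params.gamma != 0.0:
            shift = params.gamma * _index_jan_may_mean(panel, truth.active_index, year)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "tmean": seasonal + noise + shift,
                    "in_season": dates >= pd.Timestamp(year, *SEASON_START),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["burn_in_days"] = params.burn_in_days
    return out


def _log_mu(
    temps: pd.DataFrame,
    truth: SyntheticTruth,
    params: MortalityParams,
    include_rr: bool = True,
) -> pd.DataFrame:
    """Expected log mean deaths for every in-season day."""
    dates = pd.DatetimeIndex(temps["date"])
    tm = temps["tmean"].to_numpy(dtype=float)
    years = dates.year.to_numpy()
    in_season = temps["in_season"].to_numpy(dtype=bool)

    lags = np.arange(MAX_LAG_DAYS + 1)
    # lagged temperatures within each year block; constant extrapolation at
    # the block start (only burn-in rows can be affected)
    lagged = np.empty((len(tm), MAX_LAG_DAYS + 1))
    for year in np.unique(years):
        blk = np.flatnonzero(years == year)
        tb = tm[blk]
        for l in lags:
            lagged[blk, l] = tb[np.clip(np.arange(len(tb)) - l, 0, None)]
    rr = np.zeros(len(tm))
    if include_rr:
        for l in lags:
            rr += truth.rr_surface(lagged[:, l], np.full(len(tm), l))

    lo, hi = dates.min(), dates.max()
    u = (dates - lo).days / max((hi - lo).days, 1) - 0.5
    season_start = pd.to_datetime({"year": years, "month": 5, "day": 1})
    dos = (dates - pd.DatetimeIndex(season_start)).days.to_numpy(dtype=float)
    seasonality = params.season_amp * (np.sin(np.pi * np.clip(dos, 0, 152) / 152.0) - 2 / np.pi)
    weekday = np.asarray(params.weekday_effects)[dates.weekday]

    log_mu = np.log(params.baseline) + params.trend * u + seasonality + weekday + rr
    out = temps.loc[in_season, ["date", "tmean"]].copy()
    out["log_mu"] = log_mu[in_season]
    return out.reset_index(drop=True)


def simulate_mortality(
    temps: pd.DataFrame,
    truth: SyntheticTruth,
    params: MortalityParams = MortalityParams(),
    area_label: str = "synthetic",
) -> pd.DataFrame:
    """Daily death counts from the lagged exposure-response ground truth.

    Counts are negative-binomial with mean ``mu_t`` and variance
    ``overdispersion * mu_t`` (Poisson when overdispersion is 1), where
    ``log mu_t`` adds a long-term trend, within-season seasonality, a weekday
    effect and the cumulative lagged temperature contribution to the
    baseline log rate.
    """
    mu_frame = _log_mu(temps, truth, params, include_rr=True)
    if not np.all(np.isfinite(mu_frame["log_mu"])) or mu_frame["log_mu"].max() > 50:
        raise ValueError("mean model overflow; check baseline and rr_surface")
    mu = np.exp(mu_frame["log_mu"].to_numpy())
    rng = _spawn(truth.seed, 2)
    phi = truth.overdispersion
    if phi <= 1.0 + 1e-12:
        deaths = rng.poisson(mu)
    else:
        size = mu / (phi - 1.0)  # NB with variance phi * mu
        deaths = rng.negative_binomial(size, 1.0 / phi)
    out = mu_frame[["date", "tmean"]].copy()
    out["deaths"] = deaths.astype(np.int64)
    out = out[["date", "deaths", "tmean"]]
    out.attrs["area_label"] = area_label
    return out


def simulate_area(
    years: Sequence[int],
    seed: int = 0,
    active: str | None = "AMO",
    truth: SyntheticTruth | None = None,
    temp_params: TemperatureParams = TemperatureParams(),
    mort_params: MortalityParams = MortalityParams(),
    area_label: str = "synthetic",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Convenience wrapper: indices -> temperature -> mortality.

    Returns ``(daily_series, index_panel, truth)`` with the daily series
    holding only in-season (May-September) rows.
    """
    if truth is None:
        truth = default_truth(seed=seed, active_index=active)
    panel = simulate_indices(years, active=truth.active_index, seed=seed)
    temps = simulate_temperature(panel, truth, temp_params, years=years)
    daily = simulate_mortality(temps, truth, mort_params, area_label=area_label)
    return daily, panel, truth


# ---------------------------------------------------------------------------
# forward oracles


def truth_implied_af(
    temps: pd.DataFrame,
    truth: SyntheticTruth,
    params: MortalityParams = MortalityParams(),
    threshold: float | None = None,
) -> pd.DataFrame:
    """Ground-truth annual attributable fraction implied by the generator.

    Computed in the forward direction from expected deaths with and without
    the excess-risk term: for each heat day (tmean strictly above
    ``threshold``, default the true MMT) the attributable count is
    ``mu - mu0 * exp(rr_at_mmt_history)`` relative-risk-free expectation; per
    year AF = attributable deaths on heat days / expected season deaths.
    This is the infinite-replicate limit of a with/without-risk forward
    simulation.
    """
    if threshold is None:
        threshold = truth.mmt_true
    with_rr = _log_mu(temps, truth, params, include_rr=True)
    without = _log_mu(temps, truth, params, include_rr=False)
    mu = np.exp(with_rr["log_mu"].to_numpy())
    mu0 = np.exp(without["log_mu"].to_numpy())
    dates = pd.DatetimeIndex(with_rr["date"])
    tmean = with_rr["tmean"].to_numpy()
    heat = tmean > threshold
    an = np.where(heat, mu - mu0, 0.0)
    frame = pd.DataFrame({"year": dates.year, "an": an, "mu": mu, "heat": heat})
    per_year = frame.groupby("year").agg(an=("an", "sum"), total=("mu", "sum"), n_heat_days=("heat", "sum"))
    per_year["af"] = per_year["an"] / per_year["total"]
    return per_year.reset_index()[["year", "af", "an", "n_heat_days"]]


def simulate_af_from_indices(
    panel: pd.DataFrame,
    years: Sequence[int],
    truth: SyntheticTruth,
    noise_sd: float = 0.01,
    intercept: float = 0.025,
    seed: int | None = None,
) -> pd.Series:
    """Annual AF response generated directly from the stage-2 model.

    AF_i = intercept + trapezoid-integral of beta_true against the active
    index's 17-month lag curve (lag 0 = May of year i back to January of
    year i-1) + Gaussian noise.  Used to exercise the functional regression
    stage with a known coefficient independently of stage 1.
    """
    years = list(years)
    rng = _spawn(truth.seed if seed is None else seed, 3)
    lags = np.arange(17)
    w = np.ones(17)
    w[0] = w[-1] = 0.5
    signal = np.zeros(len(years))
    if truth.active_index is not None:
        beta = truth.beta_true(lags)
        key = panel.set_index(["year", "month"])[truth.active_index]
        for i, year in enumerate(years):
            # lag l = month May(year) - l
            months = [(year, 5 - l) if 5 - l >= 1 else (year - 1, 17 - l) for l in lags]
            curve = np.array([key.loc[m] for m in months])
            signal[i] = float(np.sum(w * beta * curve))
    af = intercept + signal + rng.standard_normal(len(years)) * noise_sd
    return pd.Series(af, index=pd.Index(years, name="year"), name="af")


# ---------------------------------------------------------------------------
# persistence


def write_daily_series(daily: pd.DataFrame, path: str | Path) -> None:
    out = daily.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_index_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """JSON sidecar with the scalar components of the ground truth."""
    lags = np.arange(MAX_LAG_DAYS + 1)
    grid = np.arange(0.0, 35.0 + 0.5, 0.5)
    cum = [
        float(np.sum(truth.rr_surface(np.full_like(lags, t, dtype=float), lags))) for t in grid
    ]
    payload = {
        "mmt_true": truth.mmt_true,
        "active_index": truth.active_index,
        "overdispersion": truth.overdispersion,
        "seed": truth.seed,
        "cumulative_log_rr_grid": {"temp": grid.tolist(), "value": cum},
        "beta_true_monthly": truth.beta_true(np.arange(17)).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
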