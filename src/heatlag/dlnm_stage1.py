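"""Time-varying distributed lag nonlinear model (DLNM) for daily mortality.

The exposure-response relationship between daily mean temperature and death
counts is represented by a *cross-basis*: the tensor product of a quadratic
B-spline on the temperature dimension (knots at the pooled 50th and 90th
percentiles) and a natural cubic spline on the lag dimension (two interior
knots equally spaced on the log-lag scale, maximum lag 10 days).  A linear
interaction between the cross-basis and (scaled) calendar date lets the
exposure-response surface drift over the study period, capturing long-term
adaptation.  The outcome model is a quasi-Poisson regression that further
controls for day of week, a long-term trend (natural spline of date, one
degree of freedom per decade) and within-season seasonality (natural spline
of day of season, four degrees of freedom).

From the fit one can retrieve, at any date, the overall cumulative
exposure-response curve (log relative risk summed over lags 0..10), its
minimum — the minimum mortality temperature (MMT), constrained to lie
between the 10th and 90th temperature percentiles — and delta-method
standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .spline_bases import (
    BasisMatrix,
    BasisSpec,
    bspline_basis,
    log_lag_knots,
    natural_cubic_basis,
    natural_cubic_df_knots,
)

__all__ = [
    "CrossBasis",
    "DLNMFit",
    "ExposureResponse",
    "default_var_spec",
    "default_lag_spec",
    "build_crossbasis",
    "fit_dlnm",
    "predict_exposure_response",
    "find_mmt",
    "mmt_series",
]

MAX_LAG = 10
MMT_GRID_STEP = 0.1


def default_var_spec(tmean: np.ndarray) -> BasisSpec:
    """Temperature basis: quadratic B-spline, knots at the pooled 50th/90th
    percentiles, boundary at the observed range, no intercept (the model
    intercept lives in the GLM)."""
    tmean = np.asarray(tmean, dtype=float)
    knots = tuple(np.percentile(tmean, [50, 90]))
    return BasisSpec(
        kind="bspline",
        degree=2,
        interior_knots=knots,
        boundary=(float(tmean.min()), float(tmean.max())),
        intercept=False,
    )


def default_lag_spec(max_lag: int = MAX_LAG, n_knots: int = 2) -> BasisSpec:
    """Lag basis: natural cubic spline with interior knots equally spaced on
    the log-lag scale, evaluated at integer lags 0..max_lag, intercept kept
    (standard cross-basis identifiability convention)."""
    knots = tuple(log_lag_knots(max_lag, n_knots))
    return BasisSpec(
        kind="natural-cubic",
        degree=3,
        interior_knots=knots,
        boundary=(0.0, float(max_lag)),
        intercept=True,
    )


@dataclass
class CrossBasis:
    """Cross-basis design block and the metadata needed for prediction.

    ``matrix[t, i*p + j] = sum_l Bvar_i(tmean_{t-l}) * Blag_j(l)`` —
    var-major tensor order.  Lag histories never cross the September -> May
    season gap: missing lagged temperatures at a season start are replaced by
    the season's first observed value (constant extrapolation), and such rows
    are flagged in ``incomplete_history``.
    """

    matrix: np.ndarray
    var_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int
    lag_basis_values: np.ndarray  # (max_lag+1) x p, at integer lags
    incomplete_history: np.ndarray  # bool per row
    tmean: np.ndarray
    dates: pd.DatetimeIndex

    @property
    def n_var(self) -> int:
        return self.var_spec.n_basis

    @property
    def n_lag(self) -> int:
        return self.lag_spec.n_basis

    def var_basis(self, temps: np.ndarray) -> np.ndarray:
        return bspline_basis(np.asarray(temps, dtype=float), self.var_spec).values

    @property
    def lag_sum(self) -> np.ndarray:
        """Lag basis summed over integer lags; contracting the cross-basis
        coefficients against ``kron(var_basis(x), lag_sum)`` yields the
        overall cumulative log-RR at temperature x."""
        return self.lag_basis_values.sum(axis=0)


def lagged_matrix(tmean: np.ndarray, season_id: np.ndarray, max_lag: int) -> np.ndarray:
    """n x (max_lag+1) matrix of lagged values, constant-extrapolated at the
    start of each season block."""
    tmean = np.asarray(tmean, dtype=float)
    out = np.empty((len(tmean), max_lag + 1))
    for sid in np.unique(season_id):
        blk = np.flatnonzero(season_id == sid)
        tb = tmean[blk]
        idx = np.arange(len(tb))
        for l in range(max_lag + 1):
            out[blk, l] = tb[np.clip(idx - l, 0, None)]
    return out


def build_crossbasis(
    daily: pd.DataFrame,
    var_spec: BasisSpec | None = None,
    lag_spec: BasisSpec | None = None,
    max_lag: int = MAX_LAG,
) -> CrossBasis:
    """Assemble the cross-basis from a May-September daily series.

    ``daily`` needs columns ``date`` and ``tmean``; rows must be ordered and
    unique within each season.  Knot positions default to the pooled
    whole-period percentiles of ``tmean``.
    """
    dates = pd.DatetimeIndex(daily["date"])
    if dates.duplicated().any():
        raise ValueError("duplicate dates in daily series")
    if not dates.is_monotonic_increasing:
        raise ValueError("daily series must be ordered by date")
    tmean = daily["tmean"].to_numpy(dtype=float)
    season_id = dates.year.to_numpy()
    for sid, cnt in zip(*np.unique(season_id, return_counts=True)):
        if cnt < max_lag + 1:
            raise ValueError(f"season {sid} shorter than max_lag+1 days")

    if var_spec is None:
        var_spec = default_var_spec(tmean)
    if lag_spec is None:
        lag_spec = default_lag_spec(max_lag)

    lagged = lagged_matrix(tmean, season_id, max_lag)
    vb = bspline_basis(lagged.ravel(), var_spec).values.reshape(
        len(tmean), max_lag + 1, -1
    )
    lags = np.arange(max_lag + 1, dtype=float)
    lb = natural_cubic_basis(lags, lag_spec).values  # (max_lag+1) x p
    # matrix[t, i, j] = sum_l vb[t, l, i] * lb[l, j]
    cross = np.einsum("tlv,lp->tvp", vb, lb)
    n, v, p = cross.shape

    first_of_season = np.zeros(len(tmean), dtype=bool)
    for sid in np.unique(season_id):
        blk = np.flatnonzero(season_id == sid)
        first_of_season[blk[: max_lag]] = True

    return CrossBasis(
        matrix=cross.reshape(n, v * p),
        var_spec=var_spec,
        lag_spec=lag_spec,
        max_lag=max_lag,
        lag_basis_values=lb,
        incomplete_history=first_of_season,
        tmean=tmean,
        dates=dates,
    )


# ---------------------------------------------------------------------------
# model fit


@dataclass
class DLNMFit:
    """Fitted time-varying quasi-Poisson DLNM.

    ``coef``/``vcov`` cover the full design; ``blocks`` maps named blocks
    (``intercept``, ``crossbasis``, ``interaction``, ``weekday``, ``trend``,
    ``season``) to column index arrays.  ``date_scale(date)`` maps calendar
    dates to the centred unit interval used by the interaction.
    """

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    blocks: dict[str, np.ndarray]
    date_center: pd.Timestamp
    date_span_days: float
    n_obs: int
    deviance: float
    crossbasis: CrossBasis
    temp_percentiles: tuple[float, float]  # pooled p10, p90 for the MMT bound

    def date_scale(self, date: pd.Timestamp | pd.DatetimeIndex) -> float | np.ndarray:
        delta = (pd.DatetimeIndex(np.atleast_1d(np.asarray(date, dtype="datetime64[ns]"))) - self.date_center).days
        s = delta.to_numpy(dtype=float) / self.date_span_days
        return float(s[0]) if np.isscalar(date) or isinstance(date, pd.Timestamp) else s

    def effective_cb_coef(self, at_date: pd.Timestamp) -> np.ndarray:
        base = self.coef[self.blocks["crossbasis"]]
        if "interaction" not in self.blocks:
            return base
        s = self.date_scale(pd.Timestamp(at_date))
        return base + s * self.coef[self.blocks["interaction"]]


def _design(
    cb: CrossBasis, trend_df: int, time_varying: bool = True
) -> tuple[np.ndarray, dict[str, np.ndarray], pd.Timestamp, float]:
    dates = cb.dates
    n = len(dates)
    lo, hi = dates.min(), dates.max()
    center = lo + (hi - lo) / 2
    span = float((hi - lo).days)
    s = (dates - center).days.to_numpy(dtype=float) / span  # within [-0.5, 0.5]

    X_parts: list[np.ndarray] = [np.ones((n, 1))]
    blocks: dict[str, np.ndarray] = {}
    pos = 1
    blocks["intercept"] = np.array([0])

    def add(name: str, mat: np.ndarray) -> None:
        nonlocal pos
        X_parts.append(mat)
        blocks[name] = np.arange(pos, pos + mat.shape[1])
        pos += mat.shape[1]

    add("crossbasis", cb.matrix)
    if time_varying:
        add("interaction", cb.matrix * s[:, None])
    wd = dates.weekday.to_numpy()
    add("weekday", (wd[:, None] == np.arange(1, 7)[None, :]).astype(float))
    # spline arguments rescaled to O(1) for numerical conditioning (the
    # truncated-power natural basis cubes its argument)
    t_num = (dates - lo).days.to_numpy(dtype=float) / span
    trend_spec = natural_cubic_df_knots(t_num, trend_df, intercept=False)
    add("trend", natural_cubic_basis(t_num, trend_spec).values)
    season_start = pd.to_datetime(
        {"year": dates.year, "month": 5, "day": 1}
    )
    dos = (dates - pd.DatetimeIndex(season_start)).days.to_numpy(dtype=float) / 152.0
    season_spec = natural_cubic_df_knots(dos, 4, intercept=False)
    add("season", natural_cubic_basis(dos, season_spec).values)
    return np.column_stack(X_parts), blocks, center, span


def fit_dlnm(
    cb: CrossBasis,
    deaths: np.ndarray,
    trend_df: int | None = None,
    maxiter: int = 100,
    time_varying: bool = True,
) -> DLNMFit:
    """Fit the quasi-Poisson DLNM with the time-varying interaction.

    The design stacks: intercept, cross-basis, cross-basis x scaled date,
    six weekday dummies, the long-term trend spline (df = ceil(years/10))
    and the day-of-season spline (4 df).  The dispersion is estimated from
    Pearson residuals and scales the covariance matrix; point estimates are
    identical to the plain Poisson fit.
    """
    deaths = np.asarray(deaths)
    if np.any(deaths < 0) or not np.issubdtype(deaths.dtype, np.integer):
        raise ValueError("deaths must be nonnegative integers")
    n_years = cb.dates.year.nunique()
    if trend_df is None:
        trend_df = math.ceil(n_years / 10)
    X, blocks, center, span = _design(cb, trend_df, time_varying)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify the offending block for the error message
        rank = 0
        culprit = "design"
        cols: list[int] = []
        for name, idx in blocks.items():
            cols.extend(idx.tolist())
            new_rank = np.linalg.matrix_rank(X[:, cols])
            if new_rank < len(cols):
                culprit = name
                break
            rank = new_rank
        raise ValueError(f"rank-deficient design; collinear block: {culprit}")

    model = sm.GLM(deaths, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, scale="X2")
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge; last deviance {res.deviance:.3f}")
    p10, p90 = np.percentile(cb.tmean, [10, 90])
    return DLNMFit(
        coef=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        blocks=blocks,
        date_center=center,
        date_span_days=span,
        n_obs=len(deaths),
        deviance=float(res.deviance),
        crossbasis=cb,
        temp_percentiles=(float(p10), float(p90)),
    )


# ---------------------------------------------------------------------------
# prediction


@dataclass
class ExposureResponse:
    """Overall cumulative exposure-response curve at one date."""

    at_date: pd.Timestamp
    temp_grid: np.ndarray
    cum_log_rr: np.ndarray  # centred at the curve's MMT
    se: np.ndarray
    mmt: float
    mmt_bounds: tuple[float, float]


def cumulative_curve(
    fit: DLNMFit, at_date: pd.Timestamp, temp_grid: np.ndarray
) -> np.ndarray:
    """Uncentred cumulative log-RR over lags 0..max_lag on the grid."""
    cb = fit.crossbasis
    theta = fit.effective_cb_coef(at_date).reshape(cb.n_var, cb.n_lag)
    return cb.var_basis(temp_grid) @ theta @ cb.lag_sum


def find_mmt(
    temp_grid: np.ndarray, curve: np.ndarray, bounds: tuple[float, float]
) -> float:
    """Temperature of minimum risk, constrained to [p10, p90]; grid argmin
    with ties broken toward the lower temperature."""
    lo, hi = bounds
    mask = (temp_grid >= lo) & (temp_grid <= hi)
    if not mask.any():
        raise ValueError("temperature grid does not cover the MMT bounds")
    sub = curve[mask]
    if np.allclose(sub, sub[0]):
        warnings.warn("flat exposure-response curve; MMT set to lower bound")
    return float(temp_grid[mask][np.argmin(sub)])


def predict_exposure_response(
    fit: DLNMFit,
    at_date: pd.Timestamp,
    temp_grid: np.ndarray | None = None,
) -> ExposureResponse:
    """Cumulative exposure-response curve at ``at_date``, centred at its MMT.

    Standard errors are delta-method: the contrast rows combine the base
    cross-basis block and the date interaction block scaled by the
    (centred) date; the reference temperature is the curve's own MMT, so the
    curve and its SE vanish there.
    """
    cb = fit.crossbasis
    if temp_grid is None:
        # default grid rounded inward so it stays within the basis boundary
        temp_grid = np.round(
            np.arange(
                math.ceil(cb.tmean.min() * 10) / 10,
                math.floor(cb.tmean.max() * 10) / 10 + MMT_GRID_STEP / 2,
                MMT_GRID_STEP,
            ),
            10,
        )
    temp_grid = np.asarray(temp_grid, dtype=float)
    lo_b, hi_b = cb.var_spec.boundary
    if temp_grid.min() < lo_b or temp_grid.max() > hi_b:
        warnings.warn("temperature grid outside basis boundary; values clamped")
    curve = cumulative_curve(fit, at_date, temp_grid)
    mmt = find_mmt(temp_grid, curve, fit.temp_percentiles)

    # contrast rows: kron(varbasis(x) - varbasis(mmt), lag_sum), for base and
    # interaction blocks
    vb = cb.var_basis(temp_grid) - cb.var_basis(np.array([mmt]))
    C = np.kron(vb, cb.lag_sum[None, :])  # grid x (v*p)
    s = fit.date_scale(pd.Timestamp(at_date))
    idx = np.concatenate([fit.blocks["crossbasis"], fit.blocks["interaction"]])
    V = fit.vcov[np.ix_(idx, idx)]
    rows = np.hstack([C, s * C])
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, V, rows), 0.0))

    mmt_i = int(np.argmin(np.abs(temp_grid - mmt)))
    return ExposureResponse(
        at_date=pd.Timestamp(at_date),
        temp_grid=temp_grid,
        cum_log_rr=curve - curve[mmt_i],
        se=se,
        mmt=mmt,
        mmt_bounds=fit.temp_percentiles,
    )


def mmt_series(fit: DLNMFit, years: np.ndarray | None = None) -> pd.DataFrame:
    """Year-specific MMTs from the curve retrieved at the first of July."""
    if years is None:
        years = np.unique(fit.crossbasis.dates.year)
    rows = []
    for year in years:
        er = predict_exposure_response(fit, pd.Timestamp(int(year), 7, 1))
        rows.append({"year": int(year), "mmt": er.mmt})
    return pd.DataFrame(rows)
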