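"""Heat-attributable fractions from a fitted DLNM.

Daily attributable fractions follow the backward perspective: the risk
observed on day *t* is attributed to its own past temperature exposures,

    AF_t = 1 - exp(-sum_{l=0}^{L} eta(tmean_{t-l}, l; t)),

where ``eta`` is the fitted lag-specific log relative risk under day *t*'s
effective (time-varying) coefficients, referenced to the year's minimum
mortality temperature (MMT).  Daily AFs are aggregated by year over *heat
days* only — days whose mean temperature strictly exceeds a threshold — for
four heat definitions: the year-specific MMT itself, and the constant 95th,
97.5th and 99th whole-period percentiles of summer temperature.  The annual
attributable number AN is the AF-weighted death count on heat days; the
annual AF divides AN by the total May-September deaths of the year.

Uncertainty comes from empirical confidence intervals (eCI): coefficients
are redrawn from the fit's multivariate normal approximation and the MMTs
and AFs are recomputed for every draw (the MMT percentile constraint is
re-solved per draw); the interval is the 2.5/97.5 percentile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dlnm_stage1 import MMT_GRID_STEP, DLNMFit, find_mmt

__all__ = [
    "HeatDefinition",
    "percentile_heat_definitions",
    "AttributionEngine",
    "daily_af",
    "annual_af",
    "attribution_table",
    "empirical_ci",
]

PERCENTILE_LABELS = {"p95": 95.0, "p97.5": 97.5, "p99": 99.0}


@dataclass(frozen=True)
class HeatDefinition:
    """A heat-day rule: label plus one threshold per year (°C).

    Percentile definitions carry the same whole-period threshold for every
    year; the MMT definition is year-specific.
    """

    label: str
    thresholds: dict[int, float]

    def threshold_vector(self, years: np.ndarray) -> np.ndarray:
        return np.array([self.thresholds[int(y)] for y in years])


def percentile_heat_definitions(tmean: np.ndarray, years: np.ndarray) -> list[HeatDefinition]:
    """Constant whole-period percentile thresholds (95/97.5/99)."""
    out = []
    for label, q in PERCENTILE_LABELS.items():
        thr = float(np.percentile(np.asarray(tmean, dtype=float), q))
        out.append(HeatDefinition(label, {int(y): thr for y in np.unique(years)}))
    return out


class AttributionEngine:
    """Precomputed machinery to evaluate MMTs and AFs for any coefficient
    vector of the cross-basis + interaction blocks.

    Everything that does not depend on the coefficients — the cross-basis
    rows, date scalings, the temperature grid basis and percentile heat-day
    masks — is computed once, so that eCI simulation reduces to a couple of
    matrix products per draw.
    """

    def __init__(self, fit: DLNMFit):
        self.fit = fit
        cb = fit.crossbasis
        self.cb = cb
        self.dates = cb.dates
        self.years = cb.dates.year.to_numpy()
        self.year_list = np.unique(self.years)
        self.tmean = cb.tmean
        self.s_day = fit.date_scale(cb.dates)
        self.s_july = np.array(
            [fit.date_scale(pd.Timestamp(int(y), 7, 1)) for y in self.year_list]
        )
        lo = np.floor(self.tmean.min() * 10) / 10
        hi = np.ceil(self.tmean.max() * 10) / 10
        self.grid = np.round(np.arange(lo, hi + MMT_GRID_STEP / 2, MMT_GRID_STEP), 10)
        # grid basis contracted with the lag-sum: (G, v*p) -> curve = Gmat @ theta
        vb_grid = cb.var_basis(self.grid)
        self.Gmat = np.kron(vb_grid, cb.lag_sum[None, :])
        p10, p90 = fit.temp_percentiles
        self.grid_mask = (self.grid >= p10) & (self.grid <= p90)
        self.CB = cb.matrix
        self.year_pos = np.searchsorted(self.year_list, self.years)
        blocks = [fit.blocks["crossbasis"]]
        if "interaction" in fit.blocks:
            blocks.append(fit.blocks["interaction"])
        self.idx = np.concatenate(blocks)
        self.k = len(fit.blocks["crossbasis"])

    def theta_point(self) -> tuple[np.ndarray, np.ndarray]:
        th = self.fit.coef[self.idx]
        ti = th[self.k :] if len(th) > self.k else np.zeros(self.k)
        return th[: self.k], ti

    def mmts(self, theta_b: np.ndarray, theta_i: np.ndarray) -> np.ndarray:
        """Year-specific MMTs (curve at July 1, constrained argmin)."""
        A = self.Gmat @ theta_b
        B = self.Gmat @ theta_i
        curves = A[None, :] + self.s_july[:, None] * B[None, :]
        sub = curves[:, self.grid_mask]
        return self.grid[self.grid_mask][np.argmin(sub, axis=1)]

    def daily_afs(
        self, theta_b: np.ndarray, theta_i: np.ndarray, mmts: np.ndarray
    ) -> np.ndarray:
        """Backward daily AF for every season day, referenced to the year MMT."""
        a1 = self.CB @ theta_b
        a2 = self.CB @ theta_i
        A = self.Gmat @ theta_b
        B = self.Gmat @ theta_i
        mmt_idx = np.searchsorted(self.grid, mmts[self.year_pos] - 1e-9)
        cum = a1 + self.s_day * a2 - (A[mmt_idx] + self.s_day * B[mmt_idx])
        return 1.0 - np.exp(-cum)

    def annual_table(
        self,
        afs: np.ndarray,
        deaths: np.ndarray,
        heat_defs: list[HeatDefinition],
    ) -> pd.DataFrame:
        deaths = np.asarray(deaths, dtype=float)
        totals = np.bincount(self.year_pos, weights=deaths)
        if np.any(totals <= 0):
            raise ValueError("a year has zero total season deaths")
        rows = []
        contrib = afs * deaths
        for hd in heat_defs:
            thr = hd.threshold_vector(self.year_list)[self.year_pos]
            heat = self.tmean > thr
            an = np.bincount(self.year_pos, weights=np.where(heat, contrib, 0.0))
            n_heat = np.bincount(self.year_pos, weights=heat.astype(float))
            for j, y in enumerate(self.year_list):
                rows.append(
                    {
                        "year": int(y),
                        "heat_def": hd.label,
                        "af": an[j] / totals[j],
                        "an": an[j],
                        "n_heat_days": int(n_heat[j]),
                    }
                )
        return pd.DataFrame(rows)

    def run(
        self, deaths: np.ndarray, theta_b: np.ndarray | None = None,
        theta_i: np.ndarray | None = None,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """MMT table and AF table (all four heat definitions) for one
        coefficient vector (defaults to the point estimate)."""
        if theta_b is None or theta_i is None:
            theta_b, theta_i = self.theta_point()
        mmts = self.mmts(theta_b, theta_i)
        mmt_df = pd.DataFrame({"year": self.year_list.astype(int), "mmt": mmts})
        afs = self.daily_afs(theta_b, theta_i, mmts)
        heat_defs = [HeatDefinition("MMT", dict(zip(mmt_df["year"], mmt_df["mmt"])))]
        heat_defs += percentile_heat_definitions(self.tmean, self.years)
        return mmt_df, self.annual_table(afs, deaths, heat_defs)


# ---------------------------------------------------------------------------
# functional surface


def daily_af(fit: DLNMFit, mmts: pd.DataFrame | None = None) -> pd.Series:
    """Point-estimate daily AF for every season day.

    ``mmts`` (year, mmt) defaults to the year-specific MMTs of the fit.
    Days whose lagged history sits exactly at the MMT get AF 0.
    """
    eng = AttributionEngine(fit)
    tb, ti = eng.theta_point()
    if mmts is None:
        mmt_vec = eng.mmts(tb, ti)
    else:
        mmt_vec = mmts.set_index("year")["mmt"].loc[eng.year_list].to_numpy()
    return pd.Series(eng.daily_afs(tb, ti, mmt_vec), index=eng.dates, name="af")


def annual_af(
    daily_afs: pd.Series,
    deaths: np.ndarray,
    heat_def: HeatDefinition,
    tmean: np.ndarray,
    year: int,
) -> dict:
    """Aggregate daily AFs of one year over heat days of one definition."""
    dates = pd.DatetimeIndex(daily_afs.index)
    sel = dates.year == year
    if not sel.any():
        raise ValueError(f"no season days for year {year}")
    deaths = np.asarray(deaths, dtype=float)[sel]
    total = deaths.sum()
    if total <= 0:
        raise ValueError("zero total season deaths")
    heat = np.asarray(tmean, dtype=float)[sel] > heat_def.thresholds[year]
    an = float(np.sum(daily_afs.to_numpy()[sel] * deaths * heat))
    return {
        "year": year,
        "heat_def": heat_def.label,
        "af": an / total,
        "an": an,
        "n_heat_days": int(heat.sum()),
    }


def attribution_table(fit: DLNMFit, deaths: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-estimate (mmt_table, af_table) for all four heat definitions."""
    return AttributionEngine(fit).run(np.asarray(deaths))


def empirical_ci(
    fit: DLNMFit,
    deaths: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """95% empirical confidence intervals for annual MMTs and AFs.

    Draws ``n_sim`` coefficient vectors from N(coef, vcov) restricted to the
    cross-basis and interaction blocks, recomputes the year-specific MMTs
    (with the 10th-90th percentile constraint re-solved per draw) and all
    per-year, per-definition AFs, and reports percentile 2.5/97.5 bounds
    alongside the point estimates.  Returns ``(mmt_table, annual_af_table,
    period_table)``; the last holds, per heat definition, the across-year
    mean AF with the eCI of that mean.
    """
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives unstable percentile bounds")
    eng = AttributionEngine(fit)
    deaths = np.asarray(deaths)
    mmt_df, af_df = eng.run(deaths)

    mean = fit.coef[eng.idx]
    V = fit.vcov[np.ix_(eng.idx, eng.idx)]
    w, Q = np.linalg.eigh((V + V.T) / 2)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        warnings.warn("vcov not positive semidefinite; eigenvalues floored at 0")
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    draws = mean + (rng.standard_normal((n_sim, len(mean))) * np.sqrt(w)) @ Q.T

    n_years = len(eng.year_list)
    mmt_sims = np.empty((n_sim, n_years))
    af_sims: dict[str, np.ndarray] = {}
    labels = ["MMT", *PERCENTILE_LABELS]
    for lab in labels:
        af_sims[lab] = np.empty((n_sim, n_years))
    pct_defs = percentile_heat_definitions(eng.tmean, eng.years)
    totals = np.bincount(eng.year_pos, weights=deaths.astype(float))
    pct_heat = {hd.label: eng.tmean > hd.threshold_vector(eng.year_list)[eng.year_pos]
                for hd in pct_defs}
    for r in range(n_sim):
        tb = draws[r, : eng.k]
        ti = draws[r, eng.k :] if draws.shape[1] > eng.k else np.zeros(eng.k)
        mmts = eng.mmts(tb, ti)
        mmt_sims[r] = mmts
        afs = eng.daily_afs(tb, ti, mmts)
        contrib = afs * deaths
        heat_mmt = eng.tmean > mmts[eng.year_pos]
        af_sims["MMT"][r] = (
            np.bincount(eng.year_pos, weights=np.where(heat_mmt, contrib, 0.0)) / totals
        )
        for lab, heat in pct_heat.items():
            af_sims[lab][r] = (
                np.bincount(eng.year_pos, weights=np.where(heat, contrib, 0.0)) / totals
            )

    lo, hi = np.percentile(mmt_sims, [2.5, 97.5], axis=0)
    mmt_df = mmt_df.assign(eci_lo=lo, eci_hi=hi)
    af_df = af_df.copy()
    af_df["eci_lo"] = np.nan
    af_df["eci_hi"] = np.nan
    period_rows = []
    for lab in labels:
        lo, hi = np.percentile(af_sims[lab], [2.5, 97.5], axis=0)
        sel = af_df["heat_def"] == lab
        af_df.loc[sel, "eci_lo"] = lo
        af_df.loc[sel, "eci_hi"] = hi
        mean_draws = af_sims[lab].mean(axis=1)
        plo, phi = np.percentile(mean_draws, [2.5, 97.5])
        period_rows.append(
            {
                "heat_def": lab,
                "af_mean": float(af_df.loc[sel, "af"].mean()),
                "eci_lo": float(plo),
                "eci_hi": float(phi),
            }
        )
    return mmt_df, af_df, pd.DataFrame(period_rows)
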