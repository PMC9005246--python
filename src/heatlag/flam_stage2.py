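"""Scalar-on-function regression of annual AF on climate-index curves.

The annual heat-attributable fraction is modelled as

    AF_i = sum_j  integral_0^16  beta_j(l) x_ijl dl  +  s_i  +  eps_i,

where ``x_ijl`` is the curve of monthly values of climate index *j* for year
*i* over a 17-point lag grid (lag 0 = May of year *i*, lag 16 = January of
year *i-1*), ``beta_j`` is a functional coefficient, and ``s_i`` a smooth
P-spline component of the year.  In the linear array representation each
``beta_j`` is expanded in a cubic B-spline basis on the lag grid, turning the
functional term into a penalized linear term whose design row is the
quadrature-weighted curve contracted with the basis.

Estimation is component-wise L2 gradient boosting: at each iteration every
base learner (one per index, plus the year smooth) is fitted by penalized
least squares to the current residuals and a small step ``nu`` of the best
one — lowest residual sum of squares — is added.  All base learners share the
same effective degrees of freedom so that selection is not biased toward more
flexible components.  The number of iterations is chosen by 10-fold
cross-validation; learners never selected before the stopping iteration have
an identically zero coefficient, which makes the procedure a variable
selector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spline_bases import BasisSpec, bspline_basis, pspline_penalty, uniform_pspline_basis

__all__ = [
    "N_LAGS",
    "FunctionalDesign",
    "PenalizedLearner",
    "BoostFit",
    "build_functional_design",
    "functional_base_learner",
    "year_smooth_learner",
    "scalar_learner",
    "boost",
    "pointwise_ci",
]

N_LAGS = 17  # monthly lags 0..16: May of year i back to January of year i-1


def trapezoid_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


@dataclass
class FunctionalDesign:
    """Stacked index curves and the AF response.

    ``curves[i, j, l]`` is the standardised value of index *j* at monthly lag
    *l* for year *i*; the lag axis runs recent -> past.  ``standardization``
    records the per-index mean and SD removed from the raw panel, so
    coefficient curves are effects per index standard deviation.
    """

    response: np.ndarray
    curves: np.ndarray  # n x J x N_LAGS
    index_names: list[str]
    quad_weights: np.ndarray
    years: np.ndarray
    standardization: pd.DataFrame  # index, mean, sd

    @property
    def n_years(self) -> int:
        return len(self.response)


def build_functional_design(afs: pd.Series, panel: pd.DataFrame) -> FunctionalDesign:
    """Extract per-year lag curves from the monthly index panel.

    ``afs`` is the annual AF indexed by year.  For year *i*, lag ``l`` maps to
    calendar month May(i) - l; the panel must cover January of the first
    year - 1 through May of the last year.  Each index is z-scored over all
    (year, lag) cells; quadrature weights are trapezoidal on the unit-spaced
    grid.
    """
    years = np.asarray(sorted(afs.index), dtype=int)
    names = [c for c in panel.columns if c not in ("year", "month")]
    key = panel.set_index(["year", "month"])
    curves = np.empty((len(years), len(names), N_LAGS))
    for i, year in enumerate(years):
        for l in range(N_LAGS):
            y, m = (year, 5 - l) if 5 - l >= 1 else (year - 1, 17 - l)
            try:
                row = key.loc[(y, m)]
            except KeyError:
                raise ValueError(f"panel missing month ({y}, {m}) needed for year {year}")
            curves[i, :, l] = row[names].to_numpy(dtype=float)
    means = curves.mean(axis=(0, 2))
    sds = curves.std(axis=(0, 2))
    if np.any(sds == 0):
        raise ValueError("an index is constant over the design cells")
    curves = (curves - means[None, :, None]) / sds[None, :, None]
    return FunctionalDesign(
        response=afs.loc[years].to_numpy(dtype=float),
        curves=curves,
        index_names=names,
        quad_weights=trapezoid_weights(N_LAGS),
        years=years,
        standardization=pd.DataFrame({"index": names, "mean": means, "sd": sds}),
    )


# ---------------------------------------------------------------------------
# base learners


@dataclass
class PenalizedLearner:
    """One boosting component: penalized least-squares on a design block.

    Fitting to residuals r solves ``(Z'Z + lam * P) c = Z' r``; ``lam`` is
    calibrated once so the trace of the hat matrix equals the common
    ``df_target`` (equal-df learners keep selection fair).
    """

    name: str
    Z: np.ndarray
    penalty: np.ndarray | None
    lam: float
    df: float
    lag_basis: np.ndarray | None = None  # N_LAGS x K, to rebuild beta_j(l)

    def solver(self, rows: np.ndarray | None = None) -> np.ndarray:
        """(K x n_rows) map from residuals to coefficients."""
        Z = self.Z if rows is None else self.Z[rows]
        G = Z.T @ Z
        if self.penalty is not None:
            G = G + self.lam * self.penalty
        return np.linalg.solve(G, Z.T)


def _calibrate_lambda(Z: np.ndarray, P: np.ndarray, df_target: float) -> float:
    """Penalty scale such that the hat-matrix trace equals df_target.

    With A = Z'Z = LL' and g the eigenvalues of L^{-1} P L^{-T},
    edf(lam) = tr((A + lam P)^{-1} A) = sum_i 1 / (1 + lam * g_i) — monotone
    decreasing from rank(Z) to the penalty null-space dimension; solved by
    bisection on log-lambda.
    """
    A = Z.T @ Z
    L = np.linalg.cholesky(A + 1e-12 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]))
    Linv = np.linalg.inv(L)
    g = np.linalg.eigvalsh(Linv @ P @ Linv.T)
    g = np.clip(g, 0.0, None)

    def edf(lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * g)))

    lo, hi = -16.0, 16.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if edf(10.0**mid) > df_target:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** ((lo + hi) / 2)
    if abs(edf(lam) - df_target) > 0.02:
        raise ValueError(
            f"df_target {df_target} not attainable (reachable range "
            f"[{edf(10.0**16):.2f}, {edf(10.0**-16):.2f}])"
        )
    return lam


def _lag_spline_basis(n_knots: int = 5) -> np.ndarray:
    bm = uniform_pspline_basis(
        np.arange(N_LAGS, dtype=float), 0.0, float(N_LAGS - 1), n_knots
    )
    return bm.values


def functional_base_learner(
    design: FunctionalDesign,
    j: int,
    df_target: float = 2.5,
    n_knots: int = 5,
) -> PenalizedLearner:
    """Penalized learner for the functional term of index ``j``.

    Row *i* of the design block is the quadrature-weighted curve contracted
    with the lag spline basis, ``Z[i, k] = sum_l w_l x_ijl B_k(l)``; the
    ridge penalty is a second-order difference penalty on the spline
    coefficients, scaled so the effective df equals ``df_target``.
    """
    B = _lag_spline_basis(n_knots)
    X = design.curves[:, j, :] * design.quad_weights[None, :]
    Z = X @ B
    P = pspline_penalty(B.shape[1], 2)
    lam = _calibrate_lambda(Z, P, df_target)
    return PenalizedLearner(
        name=design.index_names[j], Z=Z, penalty=P, lam=lam,
        df=df_target, lag_basis=B,
    )


def year_smooth_learner(
    years: np.ndarray, df_target: float = 2.5, n_knots: int = 20
) -> PenalizedLearner:
    """Smooth year component: dense cubic B-spline (20 interior knots) with a
    second-order difference penalty — a P-spline over the year range."""
    years = np.asarray(years, dtype=float)
    if len(np.unique(years)) < n_knots + 2:
        n_knots = max(len(np.unique(years)) - 2, 1)
        import warnings

        warnings.warn(f"too few distinct years; reducing year knots to {n_knots}")
    lo, hi = years.min(), years.max()
    bm = uniform_pspline_basis(years, lo, hi, n_knots)
    lam = _calibrate_lambda(bm.values, bm.penalty, df_target)
    return PenalizedLearner(
        name="year", Z=bm.values, penalty=bm.penalty, lam=lam, df=df_target
    )


def scalar_learner(values: np.ndarray, name: str = "summer_tmean") -> PenalizedLearner:
    """Unpenalized simple linear learner on a centred, scaled scalar (1 df)."""
    v = np.asarray(values, dtype=float)
    z = (v - v.mean()) / v.std()
    return PenalizedLearner(name=name, Z=z[:, None], penalty=None, lam=0.0, df=1.0)


# ---------------------------------------------------------------------------
# boosting


@dataclass
class BoostFit:
    """State of a fitted component-wise boosting run."""

    learners: list[PenalizedLearner]
    offset: float
    coefs: dict[str, np.ndarray]
    selected_path: list[str]
    m_stop: int
    cv_curve: np.ndarray | None
    step_length: float
    fitted: np.ndarray
    residuals: np.ndarray
    train_rows: np.ndarray

    @property
    def selected(self) -> list[str]:
        return sorted(set(self.selected_path[: self.m_stop]))

    def beta_curves(self) -> dict[str, np.ndarray]:
        """Functional coefficients beta_j(l) on the monthly lag grid (per
        standardised index unit); identically zero for unselected indices."""
        out = {}
        for lrn in self.learners:
            if lrn.lag_basis is not None:
                out[lrn.name] = lrn.lag_basis @ self.coefs[lrn.name]
        return out

    def s_hat(self) -> np.ndarray | None:
        for lrn in self.learners:
            if lrn.name == "year":
                return lrn.Z @ self.coefs["year"]
        return None

    def predict(self, rows: np.ndarray | None = None) -> np.ndarray:
        n = self.learners[0].Z.shape[0]
        rows = np.arange(n) if rows is None else rows
        pred = np.full(len(rows), self.offset)
        for lrn in self.learners:
            pred += lrn.Z[rows] @ self.coefs[lrn.name]
        return pred


def _boost_path(
    y: np.ndarray,
    learners: list[PenalizedLearner],
    train: np.ndarray,
    nu: float,
    m_max: int,
    test: np.ndarray | None = None,
):
    """Run the boosting path on ``train`` rows for ``m_max`` iterations.

    Returns (coefficient increments per iteration, chosen learner indices,
    per-iteration mean squared prediction error on ``test`` for iterations
    0..m_max if requested).
    """
    J = len(learners)
    ntr = len(train)
    S = np.empty((J, ntr, ntr))
    C = []
    Zte = []
    for q, lrn in enumerate(learners):
        Cq = lrn.solver(train)
        C.append(Cq)
        S[q] = lrn.Z[train] @ Cq
        if test is not None:
            Zte.append(lrn.Z[test])

    offset = float(y[train].mean())
    r = y[train] - offset
    picks = np.empty(m_max, dtype=int)
    incr = []
    test_mse = None
    if test is not None:
        pred_te = np.full(len(test), offset)
        test_mse = np.empty(m_max + 1)
        test_mse[0] = float(np.mean((y[test] - pred_te) ** 2))
    for m in range(m_max):
        fits = S @ r  # (J, ntr)
        rss = np.sum((r[None, :] - fits) ** 2, axis=1)
        q = int(np.argmin(rss))
        picks[m] = q
        dc = nu * (C[q] @ r)
        incr.append(dc)
        r = r - nu * fits[q]
        if test is not None:
            pred_te = pred_te + Zte[q] @ dc
            test_mse[m + 1] = float(np.mean((y[test] - pred_te) ** 2))
    return offset, picks, incr, test_mse


def boost(
    y: np.ndarray,
    learners: list[PenalizedLearner],
    nu: float = 0.1,
    m_max: int = 1000,
    cv_folds: int = 10,
    seed: int = 0,
    m_stop: int | None = None,
    train_rows: np.ndarray | None = None,
) -> BoostFit:
    """Component-wise L2 boosting with cross-validated stopping.

    When ``m_stop`` is not given, rows of ``train_rows`` (default: all) are
    assigned to ``cv_folds`` folds by a seeded permutation; the stopping
    iteration minimises the mean out-of-fold squared prediction error over
    iterations 0..m_max.  The final model is the boosting path on the full
    training rows truncated at ``m_stop``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    train_rows = np.arange(n) if train_rows is None else np.asarray(train_rows)

    cv_curve = None
    if m_stop is None:
        if len(train_rows) < 4:
            raise ValueError("need at least 4 training rows for a CV fold of >= 2")
        # cap folds so every fold keeps at least 2 observations
        cv_folds = max(2, min(cv_folds, len(train_rows) // 2))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train_rows))
        folds = np.array_split(perm, cv_folds)
        curves = np.empty((cv_folds, m_max + 1))
        for k, fold in enumerate(folds):
            te = train_rows[fold]
            tr = np.setdiff1d(train_rows, te)
            _, _, _, mse = _boost_path(y, learners, tr, nu, m_max, test=te)
            curves[k] = mse
        cv_curve = curves.mean(axis=0)
        m_stop = int(np.argmin(cv_curve))

    offset, picks, incr, _ = _boost_path(y, learners, train_rows, nu, max(m_stop, 1), None)
    coefs = {lrn.name: np.zeros(lrn.Z.shape[1]) for lrn in learners}
    path = []
    for m in range(m_stop):
        q = picks[m]
        coefs[learners[q].name] += incr[m]
        path.append(learners[q].name)
    fit = BoostFit(
        learners=learners,
        offset=offset,
        coefs=coefs,
        selected_path=path,
        m_stop=m_stop,
        cv_curve=cv_curve,
        step_length=nu,
        fitted=np.empty(0),
        residuals=np.empty(0),
        train_rows=train_rows,
    )
    fit.fitted = fit.predict(train_rows)
    fit.residuals = y[train_rows] - fit.fitted
    return fit


def default_learners(
    design: FunctionalDesign, df_target: float = 2.5
) -> list[PenalizedLearner]:
    """One functional learner per index plus the year smooth."""
    lrns = [
        functional_base_learner(design, j, df_target)
        for j in range(len(design.index_names))
    ]
    lrns.append(year_smooth_learner(design.years, df_target))
    return lrns


def pointwise_ci(
    fit: BoostFit,
    y: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> dict[str, np.ndarray]:
    """Bootstrap pointwise confidence bands for the coefficient curves.

    Years are resampled with replacement and the boosting path refitted with
    the stopping iteration held fixed at ``fit.m_stop``; bands are the
    percentile envelope of the resampled beta curves per lag.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(fit.train_rows)
    names = [l.name for l in fit.learners if l.lag_basis is not None]
    sims = {name: np.empty((n_boot, N_LAGS)) for name in names}
    for b in range(n_boot):
        rows = fit.train_rows[rng.integers(0, n, size=n)]
        bfit = boost(
            y,
            fit.learners,
            nu=fit.step_length,
            m_stop=fit.m_stop,
            train_rows=rows,
        )
        curves = bfit.beta_curves()
        for name in names:
            sims[name][b] = curves[name]
    alpha = 100 * (1 - level) / 2
    return {
        name: np.percentile(sims[name], [alpha, 100 - alpha], axis=0)
        for name in names
    }
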