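"""Spline bases shared by both modelling stages.

Three families are needed:

* quadratic/cubic **B-splines** (temperature dimension of the cross-basis,
  dense basis of the P-spline year term),
* **natural cubic splines** (lag dimension of the cross-basis, long-term
  trend and day-of-season confounder controls),
* **P-spline difference penalties** attached to dense B-spline bases.

All bases are deterministic pure functions of the evaluation points and a
:class:`BasisSpec`.  B-spline values come from the Cox–de Boor recursion as
implemented in :class:`scipy.interpolate.BSpline`; the natural cubic basis
uses the truncated-power construction that is linear beyond the boundary
knots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "uniform_pspline_basis",
    "BasisMatrix",
    "bspline_basis",
    "natural_cubic_basis",
    "log_lag_knots",
    "pspline_penalty",
    "natural_cubic_df_knots",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a univariate spline basis.

    Parameters
    ----------
    kind:
        One of ``"bspline"``, ``"natural-cubic"`` or ``"pspline"``.  A
        P-spline is a B-spline with a difference penalty attached.
    degree:
        Polynomial degree (B-spline only; natural cubic is always cubic).
    interior_knots:
        Strictly increasing knots inside the boundary interval.
    boundary:
        ``(lo, hi)`` boundary knots.  Evaluation points outside are clamped
        to the boundary value.
    penalty_order:
        Order of the difference penalty (P-spline only).
    intercept:
        If False, the first basis column is dropped so the basis can share a
        design matrix with a model intercept.
    """

    kind: str
    degree: int = 3
    interior_knots: tuple[float, ...] = ()
    boundary: tuple[float, float] = (0.0, 1.0)
    penalty_order: int = 2
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bspline", "natural-cubic", "pspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError("boundary must satisfy lo < hi")
        ks = np.asarray(self.interior_knots, dtype=float)
        if ks.size:
            if np.any(np.diff(ks) <= 0):
                raise ValueError("interior knots must be strictly increasing")
            if ks[0] <= lo or ks[-1] >= hi:
                raise ValueError("interior knots must lie strictly inside the boundary")
        if self.kind in ("bspline", "pspline") and self.degree < 1:
            raise ValueError("B-spline degree must be >= 1")

    @property
    def n_basis(self) -> int:
        """Number of columns the basis produces."""
        k = len(self.interior_knots)
        if self.kind in ("bspline", "pspline"):
            n = k + self.degree + 1
        else:  # natural cubic
            n = k + 2
        return n - (0 if self.intercept else 1)


@dataclass
class BasisMatrix:
    """Evaluated basis: an ``n_points x n_basis`` matrix plus metadata."""

    values: np.ndarray
    spec: BasisSpec
    penalty: np.ndarray | None = field(default=None)

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


def _clamp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), lo, hi)


def bspline_basis(x: np.ndarray, spec: BasisSpec) -> BasisMatrix:
    """Evaluate a B-spline basis at ``x``.

    The full basis has ``n_interior + degree + 1`` columns and satisfies the
    partition of unity inside the boundary.  Points outside the boundary are
    clamped.  For ``kind="pspline"`` a difference penalty of order
    ``spec.penalty_order`` is attached.
    """
    if spec.kind not in ("bspline", "pspline"):
        raise ValueError("spec.kind must be 'bspline' or 'pspline'")
    lo, hi = spec.boundary
    xv = _clamp(x, lo, hi)
    d = spec.degree
    knots = np.concatenate(
        [np.full(d + 1, lo), np.asarray(spec.interior_knots, float), np.full(d + 1, hi)]
    )
    dm = BSpline.design_matrix(xv, knots, d, extrapolate=False).toarray()
    penalty = None
    if spec.kind == "pspline":
        penalty = pspline_penalty(dm.shape[1], spec.penalty_order)
    if not spec.intercept:
        dm = dm[:, 1:]
        if penalty is not None:
            penalty = penalty[1:, 1:]
    return BasisMatrix(values=dm, spec=spec, penalty=penalty)


def _truncated_cubic(x: np.ndarray, knot: float, last: float, denom_knot: float) -> np.ndarray:
    # d_k(x) of the textbook natural-spline construction
    num = np.clip(x - knot, 0.0, None) ** 3 - np.clip(x - last, 0.0, None) ** 3
    return num / (last - denom_knot)


def natural_cubic_basis(x: np.ndarray, spec: BasisSpec) -> BasisMatrix:
    """Natural cubic spline basis: cubic inside, linear beyond the boundary.

    With ``K`` knots in total (interior plus the two boundary knots) the
    spline space has dimension ``K``; columns are ``1, x, N_1, ..., N_{K-2}``
    with ``N_k = d_k - d_{K-1}``, ``d_k(x) = [(x-k)_+^3 - (x-K)_+^3]/(K-k)``.
    The leading constant column is dropped when ``spec.intercept`` is False.
    Unlike the B-spline basis, evaluation is *not* clamped: the basis
    extrapolates linearly, which is the point of naturality.
    """
    if spec.kind != "natural-cubic":
        raise ValueError("spec.kind must be 'natural-cubic'")
    lo, hi = spec.boundary
    xv = np.asarray(x, dtype=float)
    knots = np.concatenate([[lo], np.asarray(spec.interior_knots, float), [hi]])
    K = len(knots)
    cols = [np.ones_like(xv), xv]
    last = knots[-1]
    second_last = knots[-2]
    d_last = _truncated_cubic(xv, second_last, last, second_last)
    for k in knots[:-2]:
        cols.append(_truncated_cubic(xv, k, last, k) - d_last)
    dm = np.column_stack(cols)
    assert dm.shape[1] == K
    if not spec.intercept:
        dm = dm[:, 1:]
    return BasisMatrix(values=dm, spec=spec, penalty=None)


def log_lag_knots(max_lag: int, n_knots: int) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale.

    ``knot_k = exp(k * log(max_lag) / (n_knots + 1))`` for ``k = 1..n_knots``,
    i.e. the knots subdivide ``(0, log(max_lag)]`` uniformly; the basis itself
    is evaluated on the original lag scale ``0..max_lag``.
    """
    if max_lag < 1 or n_knots < 1:
        raise ValueError("max_lag and n_knots must be >= 1")
    k = np.arange(1, n_knots + 1)
    return np.exp(k * math.log(max_lag) / (n_knots + 1))


def pspline_penalty(n_basis: int, order: int) -> np.ndarray:
    """Difference penalty ``D'D`` of the given order; rank ``n_basis - order``."""
    if n_basis <= order:
        raise ValueError("n_basis must exceed the penalty order")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def uniform_pspline_basis(
    x: np.ndarray,
    lo: float,
    hi: float,
    n_interior: int,
    degree: int = 3,
    penalty_order: int = 2,
) -> BasisMatrix:
    """P-spline basis on uniform *extended* knots with a difference penalty.

    Unlike the clamped-boundary B-spline, the knot grid continues at the same
    spacing ``degree`` knots beyond each boundary, so the Greville abscissae
    are equally spaced and the difference penalty exactly annihilates
    polynomial coefficient sequences up to ``penalty_order - 1`` — the
    construction of Eilers–Marx penalized splines.  ``n_interior + degree + 1``
    columns, partition of unity on ``[lo, hi]``.
    """
    if n_interior < 1:
        raise ValueError("need at least one interior knot")
    delta = (hi - lo) / (n_interior + 1)
    knots = lo + delta * np.arange(-degree, n_interior + degree + 2)
    xv = _clamp(x, lo, hi)
    dm = BSpline.design_matrix(xv, knots, degree, extrapolate=False).toarray()
    spec = BasisSpec(
        kind="pspline",
        degree=degree,
        interior_knots=tuple(lo + delta * np.arange(1, n_interior + 1)),
        boundary=(lo, hi),
        penalty_order=penalty_order,
    )
    return BasisMatrix(values=dm, spec=spec, penalty=pspline_penalty(dm.shape[1], penalty_order))


def natural_cubic_df_knots(x: np.ndarray, df: int, intercept: bool = False) -> BasisSpec:
    """Spec for a natural cubic basis with a target number of columns.

    Without an intercept a natural cubic basis with ``m`` interior knots has
    ``m + 1`` columns, so ``df`` columns require ``df - 1`` interior knots,
    placed at equally spaced quantiles of ``x`` (the convention of the usual
    regression-spline helpers); boundary knots at the observed range.
    """
    xv = np.asarray(x, dtype=float)
    m = df - 1 if not intercept else df - 2
    if m < 0:
        raise ValueError("df too small for a natural cubic basis")
    probs = np.linspace(0, 1, m + 2)[1:-1]
    interior = tuple(np.quantile(xv, probs)) if m else ()
    return BasisSpec(
        kind="natural-cubic",
        degree=3,
        interior_knots=interior,
        boundary=(float(xv.min()), float(xv.max())),
        intercept=intercept,
    )
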