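"""Truncation-point selection by the generalized marginal-standard-error rule.

A selection curve is built by evaluating the estimated standard error of the
truncated mean, sqrt(Var(mean of values[n0:])), at every candidate truncation
index.  The candidate grid excludes the final fraction of the series (10% by
default) because variance estimates from very short tails are noisy and can
produce spuriously late truncation.  Three selection modes are offered:

``min_mse``
    the earliest global minimizer of the marginal standard error (MSER);
``llm``
    the left-most local minimum of the curve, proposed to avoid
    over-truncation when the curve is noisy;
``max_ess``
    the earliest global maximizer of the effective sample size
    gamma_0 / Var(mean) over the same grid, which differs from ``min_mse``
    only through the gamma_0 factor.

Ties are always broken toward the smallest candidate, i.e. toward keeping
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import EstimatorSpec, autocovariance, variance_from_autocov, variance_of_mean
from .series import TimeSeries

__all__ = [
    "SelectionCurve",
    "TruncationResult",
    "selection_curve",
    "roster_selection_curves",
    "select_truncation",
    "select_from_curve",
    "leftmost_local_minimum",
]


@dataclass(frozen=True)
class SelectionCurve:
    """Marginal standard error evaluated over a grid of truncation candidates."""

    n0_grid: np.ndarray  # candidate truncation indices, strictly increasing
    mse: np.ndarray  # marginal standard error per candidate (observable units)
    var_mean: np.ndarray  # variance-of-mean estimate per candidate
    gamma0: np.ndarray  # lag-0 autocovariance per candidate
    max_lag_used: np.ndarray  # largest lag entering each variance sum
    spec: EstimatorSpec
    exclude_fraction: float
    stride: int

    @property
    def ess(self) -> np.ndarray:
        """Effective sample size per candidate (nan where the variance is 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.var_mean > 0, self.gamma0 / self.var_mean, np.nan)


@dataclass(frozen=True)
class TruncationResult:
    n0_star: int
    t_star: float
    ess_at_star: float
    curve: SelectionCurve
    mode: str


def selection_curve(
    series: TimeSeries,
    spec: EstimatorSpec,
    exclude_fraction: float = 0.10,
    stride: int = 1,
) -> SelectionCurve:
    """Evaluate sqrt(Var(mean)) at each candidate truncation index.

    Candidates run from 0 to ``floor((1 - exclude_fraction) * N) - 1`` in
    steps of ``stride``.  For the ``smoothed_lag_convex`` method the maximum
    lag actually used is threaded forward so that caps never increase with
    the truncation index.
    """
    grid = _candidate_grid(series.n, exclude_fraction, stride)

    var = np.empty(grid.size)
    g0 = np.empty(grid.size)
    lags = np.empty(grid.size, dtype=int)
    cap = None
    threaded = spec.method == "smoothed_lag_convex"
    for i, n0 in enumerate(grid):
        est = variance_of_mean(series, int(n0), spec, lag_cap=cap)
        var[i] = est.var_mean
        g0[i] = est.gamma0
        lags[i] = est.max_lag_used
        if threaded:
            cap = est.max_lag_used
    return SelectionCurve(
        n0_grid=grid,
        mse=np.sqrt(var),
        var_mean=var,
        gamma0=g0,
        max_lag_used=lags,
        spec=spec,
        exclude_fraction=exclude_fraction,
        stride=stride,
    )


def _candidate_grid(n: int, exclude_fraction: float, stride: int) -> np.ndarray:
    if not 0.0 <= exclude_fraction < 1.0:
        raise ValueError("exclude_fraction must lie in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    last = min(int(np.floor((1.0 - exclude_fraction) * n)) - 1, n - 2)
    if last < 0:
        raise ValueError("candidate grid is empty; series too short")
    return np.arange(0, last + 1, stride)


def roster_selection_curves(
    series: TimeSeries,
    specs: list,
    exclude_fraction: float = 0.10,
    stride: int = 1,
) -> dict:
    """Selection curves for several estimator specs in one scan.

    The full-lag autocovariance is computed once per candidate truncation
    index and shared by every spec, which is much cheaper than one scan
    per spec when several initial-sequence methods are in the roster.
    Returns ``{spec.label(): SelectionCurve}``; results are identical to
    per-spec :func:`selection_curve` calls.
    """
    grid = _candidate_grid(series.n, exclude_fraction, stride)
    k = len(specs)
    var = np.empty((k, grid.size))
    g0 = np.empty((k, grid.size))
    lags = np.empty((k, grid.size), dtype=int)
    caps: list = [None] * k
    for i, n0 in enumerate(grid):
        ac = autocovariance(series, int(n0), max_lag=series.n - int(n0) - 1)
        for j, spec in enumerate(specs):
            est = variance_from_autocov(ac, spec, lag_cap=caps[j])
            var[j, i] = est.var_mean
            g0[j, i] = est.gamma0
            lags[j, i] = est.max_lag_used
            if spec.method == "smoothed_lag_convex":
                caps[j] = est.max_lag_used
    return {
        spec.label(): SelectionCurve(
            n0_grid=grid,
            mse=np.sqrt(var[j]),
            var_mean=var[j],
            gamma0=g0[j],
            max_lag_used=lags[j],
            spec=spec,
            exclude_fraction=exclude_fraction,
            stride=stride,
        )
        for j, spec in enumerate(specs)
    }


def leftmost_local_minimum(values: np.ndarray) -> int:
    """Index of the earliest entry that is <= both of its neighbors.

    Endpoints are compared against their single neighbor.  Always returns a
    valid index (a global minimum is in particular a local one).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return 0
    for i in range(v.size):
        left_ok = i == 0 or v[i] <= v[i - 1]
        right_ok = i == v.size - 1 or v[i] <= v[i + 1]
        if left_ok and right_ok:
            return i
    return int(np.argmin(v))  # unreachable for finite input


def select_from_curve(curve: SelectionCurve, mode: str, dt: float, t0: float) -> TruncationResult:
    """Apply a selection mode to an existing curve."""
    if mode not in ("min_mse", "llm", "max_ess"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "min_mse":
        idx = int(np.argmin(curve.mse))  # argmin returns the first minimizer
    elif mode == "llm":
        idx = leftmost_local_minimum(curve.mse)
    else:
        ess = curve.ess
        with np.errstate(invalid="ignore"):
            filled = np.where(
                np.isnan(ess),
                np.where(curve.gamma0 > 0, np.inf, 0.0),
                ess,
            )
        idx = int(np.argmax(filled))
    n0_star = int(curve.n0_grid[idx])
    return TruncationResult(
        n0_star=n0_star,
        t_star=t0 + n0_star * dt,
        ess_at_star=float(curve.ess[idx]),
        curve=curve,
        mode=mode,
    )


def select_truncation(
    series: TimeSeries,
    spec: EstimatorSpec,
    mode: str = "min_mse",
    exclude_fraction: float = 0.10,
    stride: int = 1,
) -> TruncationResult:
    """Select a truncation point from the selection curve.

    ``min_mse`` takes the earliest global minimizer of the curve, ``llm``
    the left-most local minimum, ``max_ess`` the earliest global maximizer
    of the effective sample size over the same grid.
    """
    if mode not in ("min_mse", "llm", "max_ess"):
        raise ValueError(f"unknown mode {mode!r}")
    curve = selection_curve(series, spec, exclude_fraction, stride)
    return select_from_curve(curve, mode, series.dt, series.t0)
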