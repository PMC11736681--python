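"""Autocovariance estimation and variance-of-the-mean estimators.

All truncation-point heuristics in this package are instances of a single
rule — minimize the estimated standard error of the truncated mean — and
differ only in how the variance of the mean is estimated from the empirical
autocovariance function.  The estimators implemented here form a spectrum of
increasingly thorough treatments of autocorrelation:

``uncorrelated``
    gamma_0 / N: the familiar i.i.d. formula, ignoring all correlation.
``window``
    Bartlett (triangular) lag-window sum with window size ``s`` (an integer,
    or ``"sqrt"`` for floor(sqrt(N)) recomputed at each truncation point).
``initial_positive`` / ``initial_monotone`` / ``initial_convex``
    Geyer's initial-sequence estimators for reversible Markov chains,
    operating on the paired sums Gamma_m = gamma_{2m} + gamma_{2m+1}.
``chodera``
    Truncate the plain autocovariance sum at the first nonpositive term.
``smoothed_lag_convex``
    The initial-convex estimator with the Gamma series additionally capped
    at the lag used for the previous truncation point (caps never grow as
    the truncation point advances), suppressing spurious lag-index spikes.

Conventions (deliberate, and shared with the synthetic generator): the
autocovariance at every lag is divided by the truncated-series length
``N_n0`` — not ``N_n0 - t`` — and uses the truncated-sample mean, with no
bias corrections.  Under this convention the Bartlett-window and
uncorrelated estimates are nonnegative up to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.fft

from .series import TimeSeries

__all__ = [
    "AutocovSequence",
    "GammaPairs",
    "EstimatorSpec",
    "VarianceEstimate",
    "METHODS",
    "sample_mean",
    "autocovariance",
    "gamma_pairs",
    "apply_positive_rule",
    "enforce_monotone",
    "greatest_convex_minorant",
    "variance_of_mean",
    "variance_from_autocov",
    "effective_sample_size",
]

METHODS = (
    "uncorrelated",
    "window",
    "initial_positive",
    "initial_monotone",
    "initial_convex",
    "chodera",
    "smoothed_lag_convex",
)

@dataclass(frozen=True)
class AutocovSequence:
    """Lag-indexed autocovariance estimates gamma_t for a truncated series."""

    gamma: np.ndarray  # gamma[t], t = 0..max_lag, squared observable units
    n0: int  # truncation index the estimates were computed at
    n_used: int  # number of samples retained, N_n0

    @property
    def max_lag(self) -> int:
        return self.gamma.size - 1


@dataclass(frozen=True)
class GammaPairs:
    """Sums of adjacent autocovariance pairs, Gamma_m = gamma_2m + gamma_2m+1."""

    Gamma: np.ndarray
    M: int  # last retained pair index; -1 means none retained

    @property
    def retained(self) -> np.ndarray:
        return self.Gamma[: self.M + 1]


@dataclass(frozen=True)
class EstimatorSpec:
    """Which variance-of-the-mean estimator to use.

    ``window_size`` is required iff ``method == "window"`` and may be a
    positive integer or the sentinel string ``"sqrt"``.
    """

    method: str
    window_size: Optional[Union[int, str]] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; choose from {METHODS}"
            )
        if self.method == "window":
            ws = self.window_size
            if ws is None:
                raise ValueError("window method requires window_size")
            if ws != "sqrt" and (not isinstance(ws, (int, np.integer)) or ws < 1):
                raise ValueError("window_size must be a positive int or 'sqrt'")
        elif self.window_size is not None:
            raise ValueError(f"window_size is not accepted for {self.method!r}")

    def label(self) -> str:
        if self.method == "window":
            return f"window-{self.window_size}"
        return self.method


@dataclass(frozen=True)
class VarianceEstimate:
    """An estimate of Var(mean) of the truncated series."""

    var_mean: float  # squared observable units
    max_lag_used: int  # largest autocovariance lag entering the sum
    spec: EstimatorSpec
    gamma0: float = 0.0  # lag-0 autocovariance, kept for ESS


def sample_mean(series: TimeSeries, n0: int = 0) -> float:
    """Arithmetic mean of ``values[n0:]``."""
    if not 0 <= n0 <= series.n - 2:
        raise IndexError(f"n0={n0} out of range for N={series.n}")
    return float(np.mean(series.values[n0:]))


def autocovariance(
    series: TimeSeries, n0: int = 0, max_lag: Optional[int] = None
) -> AutocovSequence:
    """Empirical autocovariance of the truncated series.

    gamma_t = (1/N_n0) * sum_{i=n0}^{N-1-t} (A_i - Abar)(A_{i+t} - Abar)

    where ``Abar`` is the truncated-sample mean and the divisor is ``N_n0``
    at every lag (no finite-size or mean-bias correction).
    """
    if not 0 <= n0 <= series.n - 2:
        raise IndexError(f"n0={n0} out of range for N={series.n}")
    x = series.values[n0:]
    n_used = x.size
    if max_lag is None:
        max_lag = n_used - 1
    if not 0 <= max_lag <= n_used - 1:
        raise ValueError(f"max_lag={max_lag} exceeds N_n0 - 1 = {n_used - 1}")
    # circular-convolution autocovariance; zero-padding to >= 2*N removes wrap
    xd = x - x.mean()
    m = scipy.fft.next_fast_len(2 * n_used)
    f = scipy.fft.rfft(xd, m)
    gamma = scipy.fft.irfft(f * np.conj(f), m)[: max_lag + 1] / n_used
    return AutocovSequence(gamma=gamma, n0=n0, n_used=n_used)


def gamma_pairs(ac: AutocovSequence) -> GammaPairs:
    """Pair the autocovariance sequence: Gamma_m = gamma_2m + gamma_2m+1.

    A trailing unpaired gamma is dropped.  No positivity rule is applied
    here; ``M`` is simply the last available pair index.
    """
    if ac.gamma.size < 2:
        raise ValueError("need at least two lags to form pairs")
    n_pairs = ac.gamma.size // 2
    g = ac.gamma[: 2 * n_pairs]
    Gamma = g[0::2] + g[1::2]
    return GammaPairs(Gamma=Gamma, M=n_pairs - 1)


def apply_positive_rule(gp: GammaPairs) -> GammaPairs:
    """Terminate the pair sequence at the first nonpositive Gamma_m.

    Returns the sequence truncated to ``m <= M`` where ``M`` is the index
    just before the first violation (``M = -1`` if Gamma_0 <= 0).
    """
    bad = np.nonzero(gp.Gamma[: gp.M + 1] <= 0.0)[0]
    M = int(bad[0]) - 1 if bad.size else gp.M
    return GammaPairs(Gamma=gp.Gamma[: M + 1], M=M)


def enforce_monotone(gp: GammaPairs) -> GammaPairs:
    """Geyer's monotone rule: replace Gamma_m by the running minimum."""
    if gp.M < 0:
        return gp
    return GammaPairs(Gamma=np.minimum.accumulate(gp.Gamma[: gp.M + 1]), M=gp.M)


def greatest_convex_minorant(gp: GammaPairs) -> GammaPairs:
    """Greatest convex minorant of the (monotone) pair sequence.

    The lower convex hull of the points ``(m, Gamma_m)`` evaluated at each
    integer ``m`` — the largest convex function lying at or below the
    sequence.
    """
    if gp.M < 1:
        return gp
    y = gp.Gamma[: gp.M + 1]
    m = y.size
    # Andrew-monotone-chain lower hull over x = 0..m-1.
    hull_x: list[int] = []
    hull_y: list[float] = []
    for i in range(m):
        while len(hull_x) >= 2:
            x1, x2 = hull_x[-2], hull_x[-1]
            y1, y2 = hull_y[-2], hull_y[-1]
            # drop the middle point if it lies on or above the chord
            if (y2 - y1) * (i - x1) >= (y[i] - y1) * (x2 - x1):
                hull_x.pop()
                hull_y.pop()
            else:
                break
        hull_x.append(i)
        hull_y.append(float(y[i]))
    out = np.interp(np.arange(m), hull_x, hull_y)
    return GammaPairs(Gamma=out, M=gp.M)


def _window_size(spec: EstimatorSpec, n_used: int) -> int:
    ws = spec.window_size
    if ws == "sqrt":
        return int(math.isqrt(n_used))
    return int(ws)  # type: ignore[arg-type]


def variance_from_autocov(
    ac: AutocovSequence,
    spec: EstimatorSpec,
    lag_cap: Optional[int] = None,
) -> VarianceEstimate:
    """Dispatch a variance-of-the-mean estimate from precomputed gamma_t.

    ``ac`` must carry every lag the method may need (all lags up to
    ``n_used - 1`` for the initial-sequence and Chodera methods; at least
    the window size for window methods).  Sharing one autocovariance
    across several specs is what makes scanning a whole estimator roster
    cheap.
    """
    n_used = ac.n_used
    method = spec.method
    g0 = float(ac.gamma[0])

    if method == "uncorrelated":
        return VarianceEstimate(g0 / n_used, 0, spec, gamma0=g0)

    if method == "window":
        s = _window_size(spec, n_used)
        s_eff = min(s, n_used - 1)
        if s_eff > ac.max_lag:
            raise ValueError(
                f"window needs {s_eff} lags, autocovariance has {ac.max_lag}"
            )
        t = np.arange(1, s_eff + 1)
        w = 1.0 - t / (s + 1.0)
        total = g0 + 2.0 * float(np.dot(w, ac.gamma[1 : s_eff + 1]))
        var = total / n_used
        if var < -1e-9 * max(g0, 1e-300):
            raise FloatingPointError(
                f"Bartlett-window variance {var} negative beyond tolerance"
            )
        return VarianceEstimate(max(var, 0.0), s_eff, spec, gamma0=g0)

    if g0 == 0.0:  # degenerate constant series
        return VarianceEstimate(0.0, 0, spec, gamma0=0.0)

    if method == "chodera":
        neg = np.nonzero(ac.gamma[1:] <= 0.0)[0]
        T = int(neg[0]) + 1 if neg.size else ac.gamma.size
        var = (g0 + 2.0 * float(np.sum(ac.gamma[1:T]))) / n_used
        return VarianceEstimate(var, T - 1, spec, gamma0=g0)

    # Geyer initial-sequence family
    if ac.gamma.size < 2:
        gp = GammaPairs(Gamma=np.empty(0), M=-1)
    else:
        gp = apply_positive_rule(gamma_pairs(ac))
    if method == "smoothed_lag_convex" and lag_cap is not None:
        M_cap = (lag_cap - 1) // 2 if lag_cap >= 1 else -1
        if M_cap < gp.M:
            gp = GammaPairs(Gamma=gp.Gamma[: M_cap + 1], M=M_cap)
    if method in ("initial_monotone", "initial_convex", "smoothed_lag_convex"):
        gp = enforce_monotone(gp)
    if method in ("initial_convex", "smoothed_lag_convex"):
        gp = greatest_convex_minorant(gp)
    total = -g0 + 2.0 * float(np.sum(gp.retained))
    # Truncated pair sums can dip below zero on antithetically correlated
    # input; the population quantity is nonnegative, so floor at zero.
    var = max(total, 0.0) / n_used
    max_lag_used = 2 * gp.M + 1 if gp.M >= 0 else 0
    return VarianceEstimate(var, max_lag_used, spec, gamma0=g0)


def variance_of_mean(
    series: TimeSeries,
    n0: int = 0,
    spec: EstimatorSpec = EstimatorSpec("window", "sqrt"),
    lag_cap: Optional[int] = None,
) -> VarianceEstimate:
    """Estimate Var(mean of values[n0:]) by the requested method.

    ``lag_cap`` is only honoured by ``smoothed_lag_convex``: it carries the
    ``max_lag_used`` from the previous truncation point, so the Gamma
    series can never lengthen as the truncation point advances.
    """
    if not 0 <= n0 <= series.n - 2:
        raise ValueError(f"n0={n0} leaves fewer than 2 samples (N={series.n})")
    n_used = series.n - n0

    if spec.method == "uncorrelated":
        g0 = float(np.var(series.values[n0:]))  # == gamma_0 under the 1/N convention
        return VarianceEstimate(g0 / n_used, 0, spec, gamma0=g0)
    if spec.method == "window":
        s_eff = min(_window_size(spec, n_used), n_used - 1)
        ac = autocovariance(series, n0, max_lag=s_eff)
    else:
        ac = autocovariance(series, n0, max_lag=n_used - 1)
    return variance_from_autocov(ac, spec, lag_cap=lag_cap)


def effective_sample_size(
    series: TimeSeries, n0: int = 0, spec: EstimatorSpec = EstimatorSpec("window", "sqrt")
) -> float:
    """ESS = gamma_0 / Var(mean); equals N_n0 for the uncorrelated spec.

    Returns ``nan`` when the variance estimate is zero (degenerate input),
    a signal value distinct from any valid ESS.
    """
    est = variance_of_mean(series, n0, spec)
    if est.var_mean == 0.0:
        return float("nan")
    return est.gamma0 / est.var_mean
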