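"""Scalar time-series container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """An evenly sampled scalar observable.

    Parameters
    ----------
    values : array-like of float
        The sampled observable (e.g. a free-energy estimate in kcal/mol),
        length ``N >= 2``, all finite.
    dt : float
        Sampling interval in time units (ns by convention), ``dt > 0``.
    t0 : float
        Time of the first sample, same units as ``dt``.
    """

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if vals.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must all be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        """Number of samples ``N``."""
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + i * dt``."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Time span from first to last sample."""
        return self.dt * (self.n - 1)

    def truncated(self, n0: int) -> "TimeSeries":
        """Return the series with the first ``n0`` samples discarded."""
        if not 0 <= n0 <= self.n - 2:
            raise IndexError(f"n0={n0} out of range for N={self.n}")
        return TimeSeries(self.values[n0:], dt=self.dt, t0=self.t0 + n0 * self.dt)
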