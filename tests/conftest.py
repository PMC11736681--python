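"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from truncpoint import TimeSeries


def brute_force_autocov(values, n0, max_lag):
    """Double-loop autocovariance oracle, 1/N convention, truncated mean."""
    x = np.asarray(values, dtype=float)[n0:]
    n = x.size
    mean = x.sum() / n
    out = np.zeros(max_lag + 1)
    for t in range(max_lag + 1):
        acc = 0.0
        for i in range(n - t):
            acc += (x[i] - mean) * (x[i + t] - mean)
        out[t] = acc / n
    return out


def overlapping_batch_means_var(values, b):
    """Overlapping-batch-means estimate of Var(mean), batch size b."""
    x = np.asarray(values, dtype=float)
    n = x.size
    grand = x.mean()
    csum = np.concatenate([[0.0], np.cumsum(x)])
    batch_means = (csum[b:] - csum[:-b]) / b
    return float(np.mean((batch_means - grand) ** 2)) * b / n


def nonoverlapping_batch_means_var(values, b):
    """Nonoverlapping-batch-means estimate of Var(mean), batch size b."""
    x = np.asarray(values, dtype=float)
    n_b = x.size // b
    x = x[: n_b * b]
    means = x.reshape(n_b, b).mean(axis=1)
    grand = x.mean()
    return float(np.sum((means - grand) ** 2)) / (n_b * (n_b - 1))


def ar1_series(n, r, rng, sigma=1.0):
    """Stationary AR(1) sample with lag-1 correlation r, marginal SD sigma."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - r * r)
    for i in range(1, n):
        x[i] = r * x[i - 1] + innov[i - 1]
    return sigma * x


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def alternating():
    return TimeSeries([1.0, -1.0, 1.0, -1.0])


@pytest.fixture
def constant():
    return TimeSeries(np.full(12, 3.5))
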