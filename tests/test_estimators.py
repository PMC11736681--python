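"""Unit and property tests for the variance-of-the-mean estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from truncpoint import (
    EstimatorSpec,
    TimeSeries,
    autocovariance,
    effective_sample_size,
    sample_mean,
    variance_of_mean,
)
from truncpoint.estimators import (
    GammaPairs,
    apply_positive_rule,
    enforce_monotone,
    gamma_pairs,
    greatest_convex_minorant,
)

from conftest import ar1_series, brute_force_autocov, overlapping_batch_means_var

ALL_SPECS = [
    EstimatorSpec("uncorrelated"),
    EstimatorSpec("window", 5),
    EstimatorSpec("window", "sqrt"),
    EstimatorSpec("initial_positive"),
    EstimatorSpec("initial_monotone"),
    EstimatorSpec("initial_convex"),
    EstimatorSpec("chodera"),
    EstimatorSpec("smoothed_lag_convex"),
]


# ---------------------------------------------------------------------------
# sample mean and autocovariance
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,n0,expected",
    [
        ([5.0, 5.0, 5.0, 5.0], 0, 5.0),
        ([1.0, -1.0, 1.0, -1.0], 0, 0.0),
        ([10.0, 0.0, 0.0, 0.0], 1, 0.0),
    ],
)
def test_sample_mean(values, n0, expected):
    assert sample_mean(TimeSeries(values), n0) == pytest.approx(expected)


def test_sample_mean_rejects_out_of_range():
    with pytest.raises(IndexError):
        sample_mean(TimeSeries([1.0, 2.0, 3.0]), 2)  # leaves < 2 samples


def test_autocovariance_alternating_hand_values(alternating):
    ac = autocovariance(alternating, 0, 3)
    np.testing.assert_allclose(ac.gamma, [1.0, -0.75, 0.5, -0.25], atol=1e-14)


def test_autocovariance_zero_one_hand_values():
    ac = autocovariance(TimeSeries([0.0, 1.0, 0.0, 1.0]), 0, 1)
    np.testing.assert_allclose(ac.gamma, [0.25, -0.1875], atol=1e-14)


def test_autocovariance_constant_is_zero(constant):
    ac = autocovariance(constant, 0, 5)
    np.testing.assert_allclose(ac.gamma, 0.0, atol=1e-14)


def test_autocovariance_rejects_excess_lag():
    with pytest.raises(ValueError):
        autocovariance(TimeSeries([1.0, 2.0, 3.0]), 0, max_lag=3)


@pytest.mark.parametrize("n", [4, 7, 20, 50])
@pytest.mark.parametrize("n0", [0, 2])
def test_autocovariance_matches_brute_force(rng, n, n0):
    """FFT autocovariance equals the double-loop oracle on short series."""
    values = rng.normal(size=n)
    series = TimeSeries(values)
    max_lag = n - n0 - 1
    ac = autocovariance(series, n0, max_lag)
    oracle = brute_force_autocov(values, n0, max_lag)
    np.testing.assert_allclose(ac.gamma, oracle, atol=1e-12)


def test_autocovariance_matches_statsmodels(rng):
    """Cross-check the FFT autocovariance against an independent library
    implementation of the same (1/N, uncorrected) convention."""
    from statsmodels.tsa.stattools import acovf

    x = rng.normal(size=777)
    ac = autocovariance(TimeSeries(x), 0, 776)
    np.testing.assert_allclose(
        ac.gamma, acovf(x, adjusted=False, demean=True, fft=True), atol=1e-12
    )


# ---------------------------------------------------------------------------
# pair sums and Geyer transforms
# ---------------------------------------------------------------------------


def _pairs(values):
    return GammaPairs(Gamma=np.asarray(values, dtype=float), M=len(values) - 1)


def test_gamma_pairs_from_alternating(alternating):
    gp = gamma_pairs(autocovariance(alternating, 0, 3))
    np.testing.assert_allclose(gp.Gamma, [0.25, 0.25], atol=1e-14)


def test_gamma_pairs_drops_trailing_odd_lag():
    ac = autocovariance(TimeSeries([1.0, 2.0, 0.5, 1.5, 0.7]), 0, 2)
    gp = gamma_pairs(ac)
    assert gp.Gamma.size == 1
    assert gp.Gamma[0] == pytest.approx(ac.gamma[0] + ac.gamma[1])


def test_gamma_pairs_zero_series(constant):
    gp = gamma_pairs(autocovariance(constant, 0, 5))
    np.testing.assert_allclose(gp.Gamma, 0.0, atol=1e-14)


def test_positive_rule_stops_at_first_violation():
    gp = apply_positive_rule(_pairs([3.0, 1.0, -0.1, 2.0]))
    assert gp.M == 1
    np.testing.assert_allclose(gp.Gamma, [3.0, 1.0])


def test_positive_rule_keeps_all_when_positive():
    gp = apply_positive_rule(_pairs([3.0, 1.0, 0.5]))
    assert gp.M == 2


@pytest.mark.parametrize(
    "inp,expected",
    [
        ([3.0, 1.0, 0.5], [3.0, 1.0, 0.5]),
        ([3.0, 4.0, 1.0], [3.0, 3.0, 1.0]),
        ([1.0], [1.0]),
    ],
)
def test_enforce_monotone(inp, expected):
    np.testing.assert_allclose(enforce_monotone(_pairs(inp)).Gamma, expected)


@pytest.mark.parametrize(
    "inp,expected",
    [
        ([3.0, 1.0, 0.9], [3.0, 1.0, 0.9]),  # already convex
        ([3.0, 1.0, 0.99, 0.2], [3.0, 1.0, 0.6, 0.2]),  # hull by hand
        ([5.0, 4.0, 3.0, 2.0], [5.0, 4.0, 3.0, 2.0]),  # linear unchanged
    ],
)
def test_greatest_convex_minorant(inp, expected):
    out = greatest_convex_minorant(_pairs(inp)).Gamma
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_gcm_lies_at_or_below_and_is_convex(rng):
    y = np.sort(rng.uniform(0.1, 5.0, size=12))[::-1]
    out = greatest_convex_minorant(_pairs(y)).Gamma
    assert np.all(out <= y + 1e-12)
    diffs = np.diff(out)
    assert np.all(np.diff(diffs) >= -1e-12)  # nondecreasing slopes


# ---------------------------------------------------------------------------
# variance of the mean
# ---------------------------------------------------------------------------


def test_uncorrelated_variance_alternating(alternating):
    est = variance_of_mean(alternating, 0, EstimatorSpec("uncorrelated"))
    assert est.var_mean == pytest.approx(0.25)


def test_initial_positive_alternating_cancels(alternating):
    est = variance_of_mean(alternating, 0, EstimatorSpec("initial_positive"))
    assert est.var_mean == pytest.approx(0.0, abs=1e-14)


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label())
def test_constant_series_gives_zero_variance(constant, spec):
    est = variance_of_mean(constant, 0, spec)
    assert est.var_mean == pytest.approx(0.0, abs=1e-20)


def test_window_sqrt_size_recomputed_per_truncation(rng):
    """The sqrt window uses floor(sqrt(N_n0)) of the *truncated* length."""
    series = TimeSeries(rng.normal(size=150))
    est0 = variance_of_mean(series, 0, EstimatorSpec("window", "sqrt"))
    est100 = variance_of_mean(series, 100, EstimatorSpec("window", "sqrt"))
    assert est0.max_lag_used == 12  # floor(sqrt(150))
    assert est100.max_lag_used == 7  # floor(sqrt(50))


def test_chodera_truncates_at_first_nonpositive(rng):
    series = TimeSeries(ar1_series(300, 0.8, rng))
    ac = autocovariance(series, 0, series.n - 1)
    first_neg = np.nonzero(ac.gamma[1:] <= 0)[0][0] + 1
    est = variance_of_mean(series, 0, EstimatorSpec("chodera"))
    assert est.max_lag_used == first_neg - 1
    expected = (ac.gamma[0] + 2 * ac.gamma[1:first_neg].sum()) / series.n
    assert est.var_mean == pytest.approx(expected, rel=1e-12)


def test_smoothed_lag_cap_never_relaxes(rng):
    """A lag cap below the natural pair termination shortens the sum."""
    series = TimeSeries(ar1_series(400, 0.9, rng))
    free = variance_of_mean(series, 0, EstimatorSpec("smoothed_lag_convex"))
    capped = variance_of_mean(
        series, 0, EstimatorSpec("smoothed_lag_convex"), lag_cap=3
    )
    assert capped.max_lag_used <= 3 < free.max_lag_used
    assert capped.var_mean <= free.var_mean + 1e-12


@pytest.mark.parametrize("seed", range(5))
def test_geyer_ordering(seed):
    """IPS >= IMS >= ICS: each transform only lowers Gamma terms."""
    rng = np.random.default_rng(seed)
    series = TimeSeries(ar1_series(200, 0.6, rng))
    for n0 in (0, 37):
        v_pos = variance_of_mean(series, n0, EstimatorSpec("initial_positive"))
        v_mon = variance_of_mean(series, n0, EstimatorSpec("initial_monotone"))
        v_con = variance_of_mean(series, n0, EstimatorSpec("initial_convex"))
        assert v_pos.var_mean >= v_mon.var_mean - 1e-14
        assert v_mon.var_mean >= v_con.var_mean - 1e-14


def test_window_monotonicity_when_gammas_nonnegative(rng):
    """Larger windows give larger estimates while gamma_t >= 0 on the support."""
    # a random walk has strongly positive empirical autocovariance at all
    # moderate lags, guaranteeing the premise
    series = TimeSeries(np.cumsum(rng.normal(size=3000)))
    s2 = 40
    ac = autocovariance(series, 0, s2)
    assert np.all(ac.gamma >= 0), "fixture must satisfy the premise"
    prev = 0.0
    for s in (5, 10, 20, s2):
        est = variance_of_mean(series, 0, EstimatorSpec("window", s))
        assert est.var_mean >= prev - 1e-14
        prev = est.var_mean


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_nonnegativity_and_ess_identity(seed):
    """Estimates are nonnegative and ESS * Var(mean) recovers gamma_0."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 120))
    series = TimeSeries(rng.normal(size=n))
    g0 = float(np.var(series.values))
    for spec in ALL_SPECS:
        est = variance_of_mean(series, 0, spec)
        assert est.var_mean >= -1e-12 * g0
        ess = effective_sample_size(series, 0, spec)
        if est.var_mean > 0:
            assert ess * est.var_mean == pytest.approx(est.gamma0, rel=1e-12)


def test_ess_uncorrelated_equals_sample_count(rng):
    series = TimeSeries(rng.normal(size=83))
    assert effective_sample_size(series, 3, EstimatorSpec("uncorrelated")) == (
        pytest.approx(80.0)
    )


def test_ess_degenerate_is_nan(constant):
    assert np.isnan(effective_sample_size(constant, 0, EstimatorSpec("uncorrelated")))


def test_ess_ar1_statistical_inefficiency(rng):
    """For lag-1 correlation 0.5, ESS/N approaches (1-r)/(1+r) = 1/3."""
    series = TimeSeries(ar1_series(60_000, 0.5, rng))
    ess = effective_sample_size(series, 0, EstimatorSpec("initial_convex"))
    assert ess / series.n == pytest.approx(1.0 / 3.0, rel=0.1)


@pytest.mark.parametrize("n", [500, 2000])
def test_triangular_window_matches_overlapping_batch_means(rng, n):
    """Bartlett window of size b-1 ~ OBM at batch b, tighter as N grows."""
    b = 25
    series = TimeSeries(ar1_series(n, 0.7, rng))
    est = variance_of_mean(series, 0, EstimatorSpec("window", b - 1))
    obm = overlapping_batch_means_var(series.values, b)
    rel = abs(est.var_mean - obm) / obm
    assert rel < 8.0 * b / n


def test_estimator_spec_validation():
    with pytest.raises(ValueError):
        EstimatorSpec("window")  # window size required
    with pytest.raises(ValueError):
        EstimatorSpec("window", 0)
    with pytest.raises(ValueError):
        EstimatorSpec("uncorrelated", 5)  # size not accepted
    with pytest.raises(ValueError):
        EstimatorSpec("not_a_method")


def test_variance_rejects_too_few_samples():
    with pytest.raises(ValueError):
        variance_of_mean(TimeSeries([1.0, 2.0, 3.0]), 2, EstimatorSpec("uncorrelated"))
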