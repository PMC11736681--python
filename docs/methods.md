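# Methods

## The selection rule

Given samples `A_0 … A_{N-1}` at interval `dt`, the truncated mean
`⟨A⟩_[n0,N]` uses samples `n0 … N-1` (`N_n0 = N − n0` of them). The
generalized marginal-standard-error rule evaluates an estimate of
`Var(⟨A⟩_[n0,N])` at every candidate `n0` and selects the earliest global
minimizer of its square root. An initial transient inflates the variance
estimate at early `n0` (through the time-reversibility violation it causes
in the empirical autocovariance), while shrinking sample counts inflate it
at late `n0`; the minimum balances the two. Candidates cover
`0 … ⌊0.9·N⌋ − 1` by default: the final 10% of the series is excluded
because variance estimates from very short tails are noisy and produce
spuriously late truncation. A `stride > 1` thins the candidate grid for
speed at the cost of truncation-time resolution (the selected index is
accurate to ± stride).

Two alternative selection modes are provided. `llm` picks the left-most
local minimum of the curve instead of the global one; it exists to counter
over-truncation on noisy curves but tends toward very early truncation with
initial-sequence estimators. `max_ess` maximizes the effective sample size
`ESS = γ̂_0/Var̂(mean)` over the same grid; it differs from `min_mse` only
through the `γ̂_0` factor, so on stationary data the two nearly always
coincide, while on series contaminated by a few extreme initial samples
`min_mse` is slightly more aggressive. Ties always break toward the
smallest `n0` (keep data).

## Autocovariance conventions

All estimators consume the empirical autocovariance of the truncated
series,

```
γ̂_t = (1/N_n0) Σ_{i=n0}^{N-1-t} (A_i − Ā)(A_{i+t} − Ā),
```

with the truncated-sample mean `Ā` and divisor `N_n0` at *every* lag — no
`N_n0 − t` correction and no mean-bias correction. The uncorrected sum is
what makes the lag-window and pair-sum estimates internally consistent
(e.g. the full sum `Σ_{−(N−1)}^{N−1} γ̂_t` is exactly zero, so truncating
the sum is what creates a usable estimate). The computation is delegated to
`statsmodels.tsa.stattools.acovf(adjusted=False, fft=True)`, which
implements exactly this convention.

## The estimator family

- **uncorrelated**: `γ̂_0/N_n0`. Underestimates badly for positively
  correlated data; insensitive to bias beyond the `γ̂_0` term.
- **window(s)**: `(γ̂_0 + 2 Σ_{t=1}^{s_eff} w(t) γ̂_t)/N_n0` with the
  triangular (Bartlett-type) taper `w(t) = 1 − t/(s+1)` and
  `s_eff = min(s, N_n0 − 1)`. With `window_size="sqrt"`, `s = ⌊√N_n0⌋`
  recomputed at every candidate. The Bartlett kernel is positive
  semidefinite, so the estimate is nonnegative up to rounding, and the
  window-`(b−1)` estimate is asymptotically the overlapping-batch-means
  estimate at batch size `b` (a property the tests verify against an
  independent OBM oracle).
- **initial sequence (positive / monotone / convex)**: Geyer's estimators
  for reversible chains. Form `Γ̂_m = γ̂_2m + γ̂_2m+1` (a trailing unpaired
  lag is dropped), truncate at the first nonpositive `Γ̂_m`
  (first-violation stopping, not scan-past-gaps), then optionally enforce
  monotonicity (running minimum) and convexity (greatest convex minorant,
  computed as the lower convex hull of `(m, Γ̃_m)`); the estimate is
  `(−γ̂_0 + 2 Σ_{m≤M} Γ_m)/N_n0`. Each successive rule can only lower the
  retained `Γ` terms, giving the ordering IPS ≥ IMS ≥ ICS.
- **chodera**: `(γ̂_0 + 2 Σ_{t<T} γ̂_t)/N_n0` with `T` the first lag whose
  autocovariance is nonpositive. Related to, but not one of, the initial
  sequence rules; prone to abrupt lag-index dips that spike the selection
  curve. The adaptive speedup that evaluates the autocorrelation sparsely
  at long lags is deliberately not implemented (it trades accuracy for
  speed and worsens late truncation).
- **smoothed_lag_convex**: initial-convex, but during a selection scan the
  `Γ` series at each candidate is capped at the maximum lag used by the
  previous candidate, so lag caps never grow with `n0`. This removes the
  spurious curve minima caused by sudden lag-index recoveries.

Degenerate inputs: a constant series yields zero variance from every
method (and an ESS of `nan`, the signal value for "undefined"). On short
antithetically correlated series the initial-sequence pair sum can be
legitimately negative (e.g. `[1, −1, 1]` gives `−8/27`); because the
population quantity is nonnegative the estimate is floored at zero. For
the uncorrelated and Bartlett-window estimators, which are mathematically
nonnegative, a negative value beyond float tolerance raises an internal
error instead of being masked.

## Synthetic generator

Each synthetic series is `L·z + trend`, where `z` is i.i.d. standard
normal, `L` is the lower Cholesky factor of the banded symmetric covariance
`C[i,j] = γ(|i−j|)` (band = the model's maximum lag index), and the trend
is a biexponential transient `a_slow·2^(−t/hl_slow) + a_fast·2^(−t/hl_fast)`
parameterized by half-lives (base-2 exponentials, matching the half-life
parameterization of the preset table). The true mean is exactly 0 by
construction. One root seed spawns an independent child stream per series,
so enlarging an ensemble never reshuffles existing members. If the banded
covariance is not positive definite (possible for truncated empirical
autocovariances), escalating diagonal jitter is applied (`1e−10·γ_0`, ×10
per retry, capped at `1e−4·γ_0`) before failing with the smallest
eigenvalue named. In practice a target autocovariance should have decayed
to ≲1% of `γ_0` at its maximum lag; abrupt cuts at a few percent are
routinely indefinite.

**Model fitting.** `fit_transient` estimates the stationary mean from the
samples after the fitting window, fits a single base-2 exponential to the
head, fits a second, faster exponential to the residual, keeps it only if
its amplitude is positive, and then refines all parameters jointly. A free
additive offset is fitted and discarded at each stage; without it, the
residual tail mass of the exponential (~1e−4 for typical windows) would
contaminate noise-free parameter recovery, which is exact to better than
1e−6 with the offset. `fit_autocov_model` takes `γ̂_0, γ̂_1` directly and
reconstructs lags ≥ 2 from the initial-convex `Γ` sequence by linear
interpolation at `m_t = (t − ½)/2` with `γ_t = Γ(m_t)/2` — one admissible
reading of "interpolating the convex Γ function"; it preserves pair sums
exactly when `Γ` is linear. The interpolation clamps at the final pair for
the last odd lag. The positive-rule termination defines the model's
maximum lag index; γ is zero beyond it.

**Presets.** Five named presets mimic protein–ligand
absolute-binding-free-energy systems (T4L, MIF, MDM2-Nutlin, MDM2-Pip2,
PDE2A): the transient parameters are fitted values reported for the
reference calculations, but the full autocovariance functions are
summarized only by the implied total variance of the mean
(`γ_0 + 2Σγ_t`) and the maximum lag index. The preset
autocovariance is therefore an explicit *surrogate*: a two-component
base-2 decay (fast component: 80% of `γ_0`, half-life 5 samples; tail
half-life set so the tail reaches 1% of its initial value at the printed
maximum lag), scaled so the implied total variance matches the printed
value exactly. Surrogate ensembles reproduce the qualitative
bias/variance structure of the real systems, not their exact numbers.

**Variants** derive modified ensembles: `short` head-truncates to a stated
duration (default 0.2 ns); `subsampled` keeps every k-th point (default
100) and scales `dt`; `noisy` regenerates with all autocovariance terms
scaled (default √5) from the same seed stream, so realizations match;
`block_averaged` replaces non-overlapping blocks (default 100) by their
means, which preserves each series' grand mean exactly up to a dropped
remainder.

**What the generator does not emulate:** slow drifts of the "stationary"
level, sudden state transitions, non-Gaussian marginals, and λ-state
structure of alchemical calculations. Tests passing on these ensembles
show the heuristics behave correctly for Gaussian noise with the modeled
correlation plus a deterministic transient — not that they are robust to
every pathology of real simulation data.

## Benchmarking

Heuristics are scored by the RMSE of their truncated means to the true
mean over an ensemble, decomposed as `RMSE² = Bias² + SD²` with the
*population* SD convention so the identity is exact. Uncertainties are 95%
percentile-bootstrap intervals over resampled series (default 10 000
iterations), bootstrapping the RMSE directly. The fixed-truncation RMSE
curve supplies the optimal-fixed-point lower bound. CI coverage uses
normal quantiles (not t; with thousands of retained samples the difference
is negligible, and the variance estimate's own bias dominates).

The subsampling analysis treats a stationary series with exponential
autocorrelation `ρ_t = r^t`, `r = 2^(−1/h)` — exactly an AR(1) process.
Subsampling at the statistical inefficiency `g = (1+r)/(1−r)` (rounded to
an integer stride) multiplies `Var(mean)` by `(1+r^g)/(1−r^g)·g/g_exact`,
which tends to `coth(1) ≈ 1.313` as `h → ∞`: a ~31% inflation even though
the retained samples are nearly uncorrelated. The analytic mode evaluates
exact geometric-sum formulas (or the infinite-series limit when no length
is given); the simulated mode generates AR(1) ensembles and estimates both
variances empirically. The tests compare the two within a bootstrap
Monte-Carlo error rather than a fixed tolerance.

## Problem sizes

Ensemble tests and the acceptance script use series of 10^4 points at the
native 0.8 ps interval (8 ns) — the standard problem size of the reference
data — with ensembles of 300–500 members and a selection-grid stride of
50. These sizes were fixed as the package's own desk-scale conditions;
larger runs sharpen the statistics but do not change the orderings or
conclusions. One full ensemble scan with the complete nine-method roster
takes a few minutes on one CPU.

## Known limitations

- Single-run variance estimates are systematically low for trapped or
  quasi-nonergodic simulations; nothing here can detect mass missing from
  the sampled distribution, and none of these heuristics reliably detects
  *insufficient* sampling (a truncation time beyond 50% of the run is a
  hint, not a test).
- The exact triangular-window normalization (`1 − t/(s+1)` vs `1 − t/s`)
  is an interpretation; the chosen form keeps `w > 0` on its support and
  matches the OBM equivalence at batch size `s + 1`.
- Multi-run selection with globally centered autocovariances is out of
  scope.
- The Γ-sequence termination uses first-violation stopping; sequences with
  isolated noise-induced negative pairs terminate early, which biases
  initial-sequence variance estimates low — visible in the below-nominal
  CI coverage for strongly correlated data.
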