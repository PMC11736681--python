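# truncpoint

Truncation-point selection for autocorrelated simulation time series.

Quantities computed from molecular simulations — free-energy estimates,
observable traces — are usually biased at the start of a run by
unrepresentative initial configurations. Discarding an initial segment
reduces this bias, but discarding too much inflates the random error.
`truncpoint` selects the truncation point automatically using the
*generalized marginal standard error rule* (MSER): pick the first retained
index `n0` minimizing the estimated standard error of the truncated mean,

```
n0* = argmin_n0  sqrt( Var̂( ⟨A⟩_[n0, N] ) )
```

The heuristics in the family differ only in how `Var̂(mean)` is estimated
from the empirical autocovariance `γ̂_t` of the truncated series
(uncorrected, 1/N convention):

| method | variance-of-the-mean estimate |
|---|---|
| `uncorrelated` | `γ̂_0 / N` (White's original MSER) |
| `window` (size `s`, or `sqrt` = ⌊√N⌋) | Bartlett-window sum `(γ̂_0 + 2 Σ w(t) γ̂_t)/N`, `w(t) = 1 − t/(s+1)` |
| `initial_positive` / `_monotone` / `_convex` | Geyer initial-sequence estimators on the pair sums `Γ_m = γ̂_2m + γ̂_2m+1` |
| `chodera` | autocovariance sum truncated at the first nonpositive term |
| `smoothed_lag_convex` | initial-convex with lag caps that never grow with `n0` |

Less thorough treatment of correlation truncates too early (bias); more
thorough treatment truncates late and variably (variance). The ⌊√N⌋ window
balances the two and is the default. Maximizing the effective sample size
`ESS = γ̂_0 / Var̂(mean)` is also supported and differs from MSER only
through the `γ̂_0` factor.

The package also ships a synthetic-data generator (correlated Gaussian
series with a known true mean via banded Cholesky factorization, plus
biexponential initial transients, with presets mimicking five protein-ligand
absolute-binding-free-energy systems) and a benchmarking harness
(RMSE = √(bias² + SD²) decomposition, bootstrap confidence intervals,
fixed-truncation optimum curves, CI coverage, subsampling variance
inflation).

## Worked example

```python
import numpy as np
from truncpoint import TimeSeries, EstimatorSpec, select_truncation, variance_of_mean

rng = np.random.default_rng(7)
t = 0.002 * np.arange(4000)                      # ns
values = 3.0 * np.exp2(-t / 0.5) + rng.normal(scale=0.8, size=t.size)
series = TimeSeries(values, dt=0.002)

spec = EstimatorSpec("window", "sqrt")
res = select_truncation(series, spec, mode="min_mse")
est = variance_of_mean(series, res.n0_star, spec)
print(res.n0_star, f"{res.t_star:.3f}",
      f"{series.values[res.n0_star:].mean():.3f}",
      f"{np.sqrt(est.var_mean):.3f}", f"{res.ess_at_star:.0f}")
```

prints

```
972 1.944 0.024 0.014 3160
```

The series starts 3 units above its stationary mean with a 0.5 ns transient
half-life; the heuristic discards the first 1.9 ns (972 samples), after
which the truncated mean (0.024) is within two standard errors (0.014) of
the true mean 0, with ~3160 effectively independent samples retained.
Running `python examples/detect_truncation.py` reproduces this; the other
scripts in `examples/` demonstrate ensemble generation, benchmarking, and
the subsampling analysis.

## Command line

```bash
truncpoint detect series.csv --method window --window-size sqrt --mode min-mse
truncpoint synth --preset MDM2-Pip2 --n-series 100 --seed 7 --output ens/
truncpoint benchmark ens/ --methods all --n-boot 10000 --output results.json
```

`detect` accepts one-column (`--dt` required) or time+value delimited text.
All results are JSON with the full configuration echoed for provenance.

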