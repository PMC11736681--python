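"""Select a truncation point for a single noisy series with a transient.

Builds a short synthetic series whose first nanosecond is biased by a
decaying transient, then runs the recommended sqrt(N)-window heuristic and
prints where it would start averaging.
"""

import numpy as np

from truncpoint import EstimatorSpec, TimeSeries, select_truncation, variance_of_mean

rng = np.random.default_rng(7)
dt = 0.002  # ns
t = dt * np.arange(4000)
values = 3.0 * np.exp2(-t / 0.5) + rng.normal(scale=0.8, size=t.size)
series = TimeSeries(values, dt=dt)

spec = EstimatorSpec("window", "sqrt")
result = select_truncation(series, spec, mode="min_mse")
est = variance_of_mean(series, result.n0_star, spec)
mean = series.values[result.n0_star:].mean()

print(f"selected truncation index : {result.n0_star}")
print(f"selected truncation time  : {result.t_star:.3f} ns")
print(f"truncated mean            : {mean:.3f}")
print(f"standard error of the mean: {np.sqrt(est.var_mean):.3f}")
print(f"effective sample size     : {result.ess_at_star:.0f}")
print()
print("The series starts 3 units above its stationary mean (true mean 0,")
print("transient half-life 0.5 ns); the heuristic should discard roughly")
print("the first 1-2 ns and report a truncated mean close to 0.")
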