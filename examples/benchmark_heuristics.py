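"""Compare truncation heuristics on a strong-transient synthetic ensemble.

Scores each member of the estimator roster by the RMSE of its truncated
means against the known true mean (0), next to the optimal fixed-truncation
RMSE that no heuristic can beat.  Sizes are kept small so the script runs in
under a minute; trends match larger runs.
"""

import numpy as np

from truncpoint import (
    EstimatorSpec,
    evaluate_heuristic,
    fixed_truncation_curve,
    generate_ensemble,
    bound_vanish_presets,
)

transient, autocov = bound_vanish_presets()["MDM2-Pip2"]
ens = generate_ensemble(transient, autocov, n_series=60, n_points=2500,
                        dt=0.0008, seed=5)

roster = [
    ("uncorrelated", EstimatorSpec("uncorrelated")),
    ("window-5", EstimatorSpec("window", 5)),
    ("window-sqrt", EstimatorSpec("window", "sqrt")),
    ("initial convex", EstimatorSpec("initial_convex")),
]

fixed = fixed_truncation_curve(ens, stride=20)
print(f"optimal fixed truncation: n0={fixed.n0_opt} "
      f"({fixed.n0_opt * ens.dt:.2f} ns), RMSE={fixed.rmse_opt:.3f}")
print()
print(f"{'method':15s} {'median discard (ns)':>20s} {'RMSE':>8s}")
for name, spec in roster:
    ev = evaluate_heuristic(ens, spec, "min_mse", stride=20, n_boot=1000, seed=1)
    med_ns = float(np.median(ev.discard_times))
    print(f"{name:15s} {med_ns:20.2f} {ev.metrics.rmse:8.3f}")
print()
print("Methods that ignore correlation (uncorrelated) truncate too early and")
print("pay in bias; fuller treatments truncate later; the sqrt(N) window sits")
print("between the extremes and stays close to the fixed-truncation optimum.")
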