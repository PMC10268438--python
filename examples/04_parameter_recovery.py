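"""Parameter recovery: CI coverage and robustness to contamination.

Repeatedly simulates cohorts with known substitution effects, refits, and
reports (a) how often the 95% CIs cover the truth and (b) how much the Huber
fit outperforms OLS when 10% of outcomes carry 10x-inflated noise. A short
demo at 60 replicates; the full-scale check lives in the test suite.
"""

import numpy as np

from tuscoda import Reallocation, build_design, estimate_substitution, fit, simulate_cohort
from tuscoda.synthetic import SimulationConfig

reps = 60
covered = total = 0
for rep in range(reps):
    cohort, truth = simulate_cohort(SimulationConfig(seed=1000 + rep))
    X, y, labels = build_design(cohort)
    fitted = fit(X, y, labels, method="robust")
    for _, row in truth.true_effects.query("duration_min == 60").iterrows():
        est = estimate_substitution(fitted, truth.base,
                                    Reallocation(row["from"], row["to"], 60.0))
        covered += est.ci_low <= row["delta_true"] <= est.ci_high
        total += 1
print(f"95% CI coverage of true 60-min effects: {covered / total:.3f} "
      f"({covered}/{total} intervals)")

sq = {"ols": [], "robust": []}
for rep in range(reps):
    cohort, truth = simulate_cohort(
        SimulationConfig(seed=2000 + rep, contamination_frac=0.10)
    )
    X, y, labels = build_design(cohort)
    bt = truth.beta[["d_ilr1", "d_ilr2", "d_ilr3"]].to_numpy()
    for method in sq:
        f = fit(X, y, labels, method=method)
        b = np.array([f.coef(f"d_ilr{i+1}") for i in range(3)])
        sq[method].append(((b - bt) ** 2).sum())
for method, v in sq.items():
    print(f"{method:6s} ilr-change coefficient RMSE under contamination: "
          f"{np.sqrt(np.mean(v)):.2f}")
# Coverage near 0.95 says the sandwich-covariance CIs are calibrated; the
# robust RMSE sits well below OLS because Huber weights cap gross outliers.
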