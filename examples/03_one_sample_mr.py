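"""One-sample MR with 2SLS: confounded OLS vs instrumented estimates.

The simulated truth is beta_XY = 0.2 with positive confounding, so plain
OLS of outcome on exposure lands near 0.32 while a valid genetic instrument
recovers ~0.2.
"""

import numpy as np

from jackmr import (
    SimulationParams,
    external_prs,
    rank_inverse_normal,
    simulate_scenario_pair,
    tsls_fit,
)

params = SimulationParams(n_applied=20_000, n_external=20_000, n_snp=200, seed=3)
rng = np.random.default_rng(params.seed)
applied, external = simulate_scenario_pair(params, rng)

y = rank_inverse_normal(applied.outcome)  # per-SD-of-outcome scale
x = applied.exposure

xc = x - x.mean()
ols = (xc @ y) / (xc @ xc)
print(f"confounded OLS slope: {ols:.3f}  (true effect 0.2 + confounding)")

score = external_prs(applied, external, threshold=5e-8)
fit = tsls_fit(y, x, score, true_value=params.beta_xy)
print(f"2SLS with external PRS ({score.n_snps_used} SNPs):")
print(f"  beta = {fit.beta_hat:.3f}  SE = {fit.se:.4f}  "
      f"95% CI [{fit.ci_low:.3f}, {fit.ci_high:.3f}]")
print(f"  first-stage F = {fit.fstat:.0f}, instrument R^2_adj = {fit.r2_adj:.4f}")
print("\nThe instrumented estimate sits near the simulated truth (0.2 per SD"
      "\nof outcome) while OLS is pulled upward by the shared confounder.")
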