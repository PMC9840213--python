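"""Build the three polygenic-score instruments and compare their in-sample fit.

The overlapping-sample score is expected to fit the exposure better than the
cross-fitted (jackknife) score on the same data — that surplus is
overfitting, not signal.
"""

import numpy as np

from jackmr import (
    SimulationParams,
    adjusted_r2,
    external_prs,
    jackknife_prs,
    overlap_prs,
    simulate_scenario_pair,
)

params = SimulationParams(
    n_applied=10_000, n_external=10_000, n_snp=200, n_block=10, seed=2
)
rng = np.random.default_rng(params.seed)
applied, external = simulate_scenario_pair(params, rng)

threshold = 0.05
ext = external_prs(applied, external, threshold)
ovl = overlap_prs(applied, threshold)
jk, per_block_weights, blocks = jackknife_prs(
    applied, params.n_block, threshold, rng
)

print(f"selection threshold P <= {threshold}")
for score in (ext, ovl, jk):
    r2 = adjusted_r2(applied.exposure, score)
    print(f"  {score.framework:>9}: {score.n_snps_used:3d} SNPs, "
          f"adjusted R^2(score, exposure) = {r2:.4f}")
print("\nThe overlap score's higher R^2 is inflated by fitting its own "
      "sample's noise;\nthe jackknife score removes that by never scoring an "
      "individual with weights\nestimated from their own data "
      f"(per-block SNP counts: {[len(w) for w in per_block_weights]}).")
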