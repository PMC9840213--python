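"""A miniature simulation study with Monte-Carlo metrics and a zipper table.

Runs a small primary-style grid (three frameworks, two thresholds) and
summarizes bias, SE calibration and CI coverage per framework.
"""

from jackmr import ScenarioGrid, SimulationParams, run_primary_grid, zipper_table

grid = ScenarioGrid(
    name="mini",
    base=SimulationParams(
        n_applied=4_000, n_external=4_000, n_snp=100,
        thresholds=(1e-4, 0.05),
    ),
    reps=50,
)
per_rep, metrics = run_primary_grid(grid, seed=5)

cols = ["framework", "threshold", "beta_mean", "beta_bias", "beta_empirical_se",
        "beta_model_se", "beta_coverage", "r2_mean"]
print(metrics[cols].round(4).to_string(index=False))
print("\nbeta_* summarize the 2SLS estimates against the true 0.2 (per SD of"
      "\noutcome, hence ~0.195 for unbiased arms); r2_mean is the instrument-"
      "\nexposure fit. Note the overlap arm's higher r2_mean, upward beta_bias"
      "\nand sub-nominal coverage.")

fits = per_rep[(per_rep.framework == "overlap") & (per_rep.threshold == 0.05)]
zip_tab = zipper_table(fits, true_value=0.2, fraction=0.2)
print("\nworst 20% of overlap replicates by |z| (zipper-plot rows):")
print(zip_tab.head(5).round(3).to_string(index=False))
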