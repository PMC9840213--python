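"""Multivariable 2SLS: separating direct from mediated effects.

Synthetic mediation: an early-life exposure affects the outcome only
through an adult exposure.  Univariable MR of the early exposure shows the
total (mediated) effect; multivariable MR, instrumenting both exposures,
shows the direct effect is ~0.
"""

import numpy as np

from jackmr import (
    SimulationParams,
    allocate_true_effects,
    simulate_cohort,
    tsls_fit,
    tsls_multivariable,
)

p = SimulationParams(n_applied=30_000, n_external=30_000, n_snp=80, seed=4)
rng = np.random.default_rng(p.seed)

b_child = allocate_true_effects(p, rng)
child = simulate_cohort(p, b_child, "applied", rng)
x_child = child.exposure
g_adult = simulate_cohort(p, b_child, "external", rng).genotypes
b_adult = allocate_true_effects(p, rng)
x_adult = 0.6 * x_child + g_adult @ b_adult + 0.7 * rng.standard_normal(p.n_applied)
y = 0.5 * x_adult + rng.standard_normal(p.n_applied)

z_child = child.genotypes @ b_child
z_adult = g_adult @ b_adult

total = tsls_fit(y, x_child, z_child)
print(f"univariable (total) effect of early exposure: "
      f"{total.beta_hat:.3f} [{total.ci_low:.3f}, {total.ci_high:.3f}]"
      f"  (truth: 0.6*0.5 = 0.30)")

multi = tsls_multivariable(y, [x_child, x_adult], [z_child, z_adult])
print("multivariable (direct) effects accounting for the other exposure:")
for name, b, lo, hi, f in zip(("early", "adult"), multi.beta_hat,
                              multi.ci_low, multi.ci_high, multi.fstat):
    print(f"  {name}: {b:6.3f} [{lo:.3f}, {hi:.3f}]  conditional F = {f:.0f}")
print("\nThe early exposure's direct effect vanishes once the adult exposure"
      "\nis in the model: its univariable effect was entirely mediated.")
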