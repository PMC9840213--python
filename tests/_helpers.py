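"""Shared test fixtures-as-code: small oracles and cohort surgery."""

import numpy as np

from jackmr.simulate import Cohort

# 8-observation 2SLS fixture: outcome, exposure, instrument (fixed values)
TOY_Y = np.array([1.2, 0.8, 2.1, 1.7, 0.3, 2.6, 1.1, 1.9])
TOY_X = np.array([0.5, 0.1, 1.4, 1.0, -0.3, 1.8, 0.4, 1.2])
TOY_Z = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0, 1.0, 2.0])


def tsls_oracle(y, x, z):
    """Explicit two-stage computation with the observed-exposure variance
    correction, independent of the package's linear algebra."""
    n = len(y)
    A = np.column_stack([np.ones(n), z])
    xhat = A @ np.linalg.solve(A.T @ A, A.T @ x)
    B = np.column_stack([np.ones(n), xhat])
    g2 = np.linalg.solve(B.T @ B, B.T @ y)
    beta = g2[1]
    resid = y - np.column_stack([np.ones(n), x]) @ g2
    sigma2 = resid @ resid / (n - 2)
    cov = sigma2 * np.linalg.inv(B.T @ B)
    return beta, np.sqrt(cov[1, 1])


def subcohort(cohort, idx):
    """Copy of a cohort restricted to the given row indices."""
    return Cohort(
        genotypes=cohort.genotypes[idx],
        exposure=cohort.exposure[idx],
        confounder=cohort.confounder[idx],
        true_effects=cohort.true_effects,
        role=cohort.role,
        outcome=None if cohort.outcome is None else cohort.outcome[idx],
    )
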