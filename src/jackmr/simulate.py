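"""Synthetic cohort generation under an additive genetic + confounder model.

Each cohort carries an n x m dosage matrix of independent biallelic SNPs
(dosages 0/1/2, drawn Binomial(2, af)), a standard-normal confounder U, a
continuous exposure

    X = sum_j b_j G_j + beta_ux * U + eps_X,

and (applied cohorts only) an outcome

    Y = beta_xy * X + beta_uy * U + eps_Y.

The per-SNP effects b_j are rescaled so the genetic component explains exactly
``var_exp`` of the exposure variance under Hardy-Weinberg dosage variance
2*af*(1-af).  Residual variances follow a variance-budget convention: each
phenotype's direct inputs are treated as independent unit-variance
contributors, giving Var(X) = 1 exactly and Var(Y) slightly above 1 (the
exposure-confounder covariance is not budgeted; see
``SimulationParams.residual_var_outcome``).  All randomness flows through a single ``numpy.random.Generator``;
identical parameters and generator state reproduce cohorts bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SimulationParams",
    "Cohort",
    "allocate_true_effects",
    "simulate_cohort",
    "simulate_scenario_pair",
    "write_cohort",
    "read_cohort",
    "read_params",
    "write_params",
]

#: The 13 P-value cutoffs of the primary threshold grid, from genome-wide
#: significance down to no filtering at all.
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 5e-4, 1e-3, 5e-3, 0.01, 0.05, 0.1, 0.5, 1.0,
)


class InvalidParametersError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass(frozen=True)
class SimulationParams:
    """Generative and design parameters for one simulation scenario.

    Defaults are the primary-study conditions: two cohorts of 50 000
    individuals, 500 independent SNPs at effect-allele frequency 0.2 jointly
    explaining 10% of exposure variance, confounding paths 0.4 (to exposure)
    and 0.3 (to outcome), a true causal effect of 0.2, and 10 jackknife
    blocks.
    """

    n_applied: int = 50_000
    n_external: int = 50_000
    n_snp: int = 500
    af: float = 0.2
    var_exp: float = 0.1
    beta_xy: float = 0.2
    beta_ux: float = 0.4
    beta_uy: float = 0.3
    n_block: int = 10
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int | None = None
    effect_mode: Literal["gaussian", "equal"] = "gaussian"

    def __post_init__(self) -> None:
        if not (0.0 < self.af < 1.0):
            raise InvalidParametersError(f"af must be in (0, 1), got {self.af}")
        if not (0.0 <= self.var_exp < 1.0):
            raise InvalidParametersError(
                f"var_exp must be in [0, 1), got {self.var_exp}"
            )
        if self.n_applied <= 0 or self.n_external <= 0:
            raise InvalidParametersError("cohort sizes must be positive")
        if self.n_snp <= 0:
            raise InvalidParametersError("n_snp must be positive")
        if self.n_block < 2:
            raise InvalidParametersError(f"n_block must be >= 2, got {self.n_block}")
        if any(not (0.0 < t <= 1.0) for t in self.thresholds):
            raise InvalidParametersError("thresholds must all lie in (0, 1]")
        if self.residual_var_exposure <= 0.0:
            raise InvalidParametersError(
                "var_exp + beta_ux^2 must be < 1 so the exposure residual "
                "variance is positive"
            )
        object.__setattr__(self, "thresholds", tuple(self.thresholds))

    @property
    def residual_var_exposure(self) -> float:
        """Residual variance of X so that Var(X) = 1 with Var(U) = 1."""
        return 1.0 - self.var_exp - self.beta_ux**2

    @property
    def residual_var_outcome(self) -> float:
        """Residual variance of Y under the variance-budget convention.

        The outcome's direct inputs (exposure and confounder) are treated as
        independent unit-variance contributors, so the residual gets
        1 - beta_xy^2 - beta_uy^2 (floored at a small positive value).
        Because X and U are in fact correlated (Cov = beta_ux), the realized
        Var(Y) is slightly above one — 1.048 at the defaults.  The analysis
        pipeline rank-normalizes the outcome before MR, so causal estimates
        are expressed per SD of the outcome; see docs/methods.md.
        """
        v = 1.0 - self.beta_xy**2 - self.beta_uy**2
        return max(v, 1e-6)

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Cohort:
    """One simulated cohort: genotypes, phenotypes and the generating truth.

    ``genotypes`` is an n x m float array with entries in {0, 1, 2} (kept as
    floats so downstream linear algebra never re-converts).  ``outcome`` is
    ``None`` for external (discovery-only) cohorts.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    confounder: np.ndarray
    true_effects: np.ndarray
    role: Literal["applied", "external"]
    outcome: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    def __post_init__(self) -> None:
        n = self.genotypes.shape[0]
        for name in ("exposure", "confounder"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match genotype rows")
        if self.role == "applied":
            if self.outcome is None or len(self.outcome) != n:
                raise ValueError("applied cohorts carry an outcome of length n")
        elif self.outcome is not None:
            raise ValueError("external cohorts carry no outcome")


def allocate_true_effects(
    params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-SNP effects whose joint explained variance is exactly var_exp.

    In the default ``gaussian`` mode raw effects are standard-normal draws
    rescaled so that ``sum_j 2*af*(1-af)*b_j**2 == var_exp`` holds to machine
    precision; in ``equal`` mode all SNPs share one magnitude.  ``var_exp=0``
    returns the zero vector.
    """
    m = params.n_snp
    if params.var_exp == 0.0:
        # advance the stream identically in both modes so downstream draws
        # do not depend on var_exp
        if params.effect_mode == "gaussian":
            rng.standard_normal(m)
        return np.zeros(m)
    var_dose = 2.0 * params.af * (1.0 - params.af)
    if params.effect_mode == "equal":
        b = np.full(m, np.sqrt(params.var_exp / (m * var_dose)))
    else:
        raw = rng.standard_normal(m)
        b = raw * np.sqrt(params.var_exp / (var_dose * np.sum(raw**2)))
    return b


def _draw_genotypes(
    n: int, m: int, af: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial(2, af) dosages via inverse CDF on 32-bit uniforms.

    P(g = 0) = (1-af)^2, P(g <= 1) = (1-af)^2 + 2 af (1-af); thresholds are
    quantized to 2^-32, i.e. exact for practical purposes, and the draw is
    ~4x faster than `rng.binomial` at the matrix sizes used here.
    """
    q0 = (1.0 - af) ** 2
    q1 = q0 + 2.0 * af * (1.0 - af)
    t0 = int(round(q0 * 2.0**32))
    t1 = int(round(q1 * 2.0**32))
    u = rng.integers(0, 2**32, size=(n, m), dtype=np.uint32)
    # two bool arrays must not meet in `np.add` (bool+bool is logical OR)
    g = (u >= t0).astype(np.float64)
    g += u >= t1
    return g


def simulate_cohort(
    params: SimulationParams,
    effects: np.ndarray,
    role: Literal["applied", "external"],
    rng: np.random.Generator,
    n: int | None = None,
) -> Cohort:
    """Simulate one cohort under the additive model.

    ``n`` overrides the role's default size (used by the external-GWAS
    sample-size sweep).  Genotypes, confounder and residuals are fresh draws
    on every call; only ``effects`` is shared between paired cohorts.
    """
    if len(effects) != params.n_snp:
        raise InvalidParametersError("effects length must equal n_snp")
    if n is None:
        n = params.n_applied if role == "applied" else params.n_external
    if n <= 0:
        raise InvalidParametersError("cohort size must be positive")

    g = _draw_genotypes(n, params.n_snp, params.af, rng)
    u = rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    x = g @ effects + params.beta_ux * u
    x += np.sqrt(params.residual_var_exposure) * eps_x

    outcome = None
    if role == "applied":
        eps_y = rng.standard_normal(n)
        outcome = (
            params.beta_xy * x
            + params.beta_uy * u
            + np.sqrt(params.residual_var_outcome) * eps_y
        )
    return Cohort(
        genotypes=g,
        exposure=x,
        confounder=u,
        true_effects=np.asarray(effects, dtype=float),
        role=role,
        outcome=outcome,
    )


def simulate_scenario_pair(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[Cohort, Cohort]:
    """Simulate one applied/external cohort pair sharing true SNP effects."""
    effects = allocate_true_effects(params, rng)
    applied = simulate_cohort(params, effects, "applied", rng)
    external = simulate_cohort(params, effects, "external", rng)
    return applied, external


# ---------------------------------------------------------------------------
# plain-text IO (debugging / fixtures; the pipeline passes cohorts in memory)

def write_cohort(cohort: Cohort, genotype_path, phenotype_path) -> None:
    np.savetxt(genotype_path, cohort.genotypes, fmt="%d", delimiter="\t")
    cols = {
        "sample_id": np.arange(cohort.n),
        "exposure": cohort.exposure,
        "confounder": cohort.confounder,
    }
    if cohort.outcome is not None:
        cols["outcome"] = cohort.outcome
    pd.DataFrame(cols).to_csv(phenotype_path, sep="\t", index=False,
                              float_format="%.17g")


def read_cohort(genotype_path, phenotype_path, true_effects=None) -> Cohort:
    g = np.loadtxt(genotype_path, delimiter="\t", ndmin=2)
    pheno = pd.read_csv(phenotype_path, sep="\t", float_precision="round_trip")
    has_outcome = "outcome" in pheno.columns
    if true_effects is None:
        true_effects = np.zeros(g.shape[1])
    return Cohort(
        genotypes=g,
        exposure=pheno["exposure"].to_numpy(),
        confounder=pheno["confounder"].to_numpy(),
        true_effects=np.asarray(true_effects, dtype=float),
        role="applied" if has_outcome else "external",
        outcome=pheno["outcome"].to_numpy() if has_outcome else None,
    )


def write_params(params: SimulationParams, path, **extra) -> None:
    """Write a flat key-value config (YAML) for a scenario."""
    d = {
        "n_applied": params.n_applied,
        "n_external": params.n_external,
        "n_snp": params.n_snp,
        "af": params.af,
        "var_exp": params.var_exp,
        "beta_xy": params.beta_xy,
        "beta_ux": params.beta_ux,
        "beta_uy": params.beta_uy,
        "n_block": params.n_block,
        "thresholds": list(params.thresholds),
        "seed": params.seed,
        "effect_mode": params.effect_mode,
    }
    d.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_params(path) -> tuple[SimulationParams, dict]:
    """Read a config file; returns (params, leftover keys such as reps/name)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    fields = {f for f in SimulationParams.__dataclass_fields__}
    kwargs = {k: v for k, v in d.items() if k in fields}
    if "thresholds" in kwargs and kwargs["thresholds"] is not None:
        kwargs["thresholds"] = tuple(kwargs["thresholds"])
    extra = {k: v for k, v in d.items() if k not in fields}
    return SimulationParams(**kwargs), extra
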