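"""Monte-Carlo performance metrics over replicate estimate tables.

Given per-replicate estimates (and, for effect estimates, their model-based
standard errors) and the true parameter value, computes the standard
simulation-study summaries: bias, empirical SE, average model-based SE,
relative error in model SE, MSE, coverage and bias-eliminated coverage of
nominal 95% intervals, each with its Monte Carlo standard error.  Formulas
follow the established simulation-summary methodology (as implemented by
e.g. the rsimsum R package):

    bias        = mean(b) - beta            MCSE = empSE / sqrt(R)
    empSE       = SD(b)  (R-1 denominator)  MCSE = empSE / sqrt(2(R-1))
    modelSE     = sqrt(mean(se^2))          MCSE = sqrt(Var(se^2)/(4 R modelSE^2))
    relerr%     = 100 (modelSE/empSE - 1)
    MSE         = mean((b - beta)^2)        MCSE = sqrt(Var((b-beta)^2)/R)
    coverage    = mean(|b - beta| <= 1.96 se)   MCSE = sqrt(c(1-c)/R)

Bias-eliminated coverage replaces beta by mean(b).  The identity
MSE = bias^2 + empSE^2 (R-1)/R holds exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .mr import Z95

__all__ = ["MetricsRow", "summarize_estimates", "summarize_r2", "zipper_table"]


@dataclass
class MetricsRow:
    """Summary of one scenario cell (framework x threshold x grid axes)."""

    n_reps: int
    mean: float
    median: float
    bias: float
    bias_mcse: float
    empirical_se: float
    empirical_se_mcse: float
    mse: float
    mse_mcse: float
    model_se: float = np.nan
    model_se_mcse: float = np.nan
    relative_error_model_se: float = np.nan
    coverage: float = np.nan
    coverage_mcse: float = np.nan
    bias_eliminated_coverage: float = np.nan
    bias_eliminated_coverage_mcse: float = np.nan
    precision_gain_vs_external: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def _basic(est: np.ndarray, true_value: float) -> dict:
    r = len(est)
    mean = est.mean()
    emp_se = est.std(ddof=1)
    err2 = (est - true_value) ** 2
    mse = err2.mean()
    return {
        "n_reps": r,
        "mean": float(mean),
        "median": float(np.median(est)),
        "bias": float(mean - true_value),
        "bias_mcse": float(emp_se / np.sqrt(r)),
        "empirical_se": float(emp_se),
        "empirical_se_mcse": float(emp_se / np.sqrt(2.0 * (r - 1))),
        "mse": float(mse),
        "mse_mcse": float(err2.std(ddof=1) / np.sqrt(r)),
    }


def summarize_estimates(
    estimates: pd.DataFrame | None = None,
    true_value: float = 0.0,
    *,
    beta_hat: np.ndarray | None = None,
    se: np.ndarray | None = None,
) -> MetricsRow:
    """Summarize per-replicate effect estimates against the true value.

    Accepts either a DataFrame with ``beta_hat`` and ``se`` columns or the
    two arrays directly.  Any non-finite estimate or SE is an error that
    names the offending replicate; upstream code records failed replicates
    as NA and excludes them (with a count) before calling this.
    """
    if estimates is not None:
        beta_hat = estimates["beta_hat"].to_numpy(dtype=float)
        se = estimates["se"].to_numpy(dtype=float)
    b = np.asarray(beta_hat, dtype=float)
    s = np.asarray(se, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 replicates")
    bad = np.flatnonzero(~(np.isfinite(b) & np.isfinite(s)))
    if len(bad):
        raise ValueError(f"non-finite estimate or SE at replicate index {bad[0]}")
    d = _basic(b, true_value)
    r = d["n_reps"]
    model_se = float(np.sqrt(np.mean(s**2)))
    var_se2 = float(np.var(s**2, ddof=1)) if r > 1 else 0.0
    covered = np.abs(b - true_value) <= Z95 * s
    be_covered = np.abs(b - b.mean()) <= Z95 * s
    cov = float(covered.mean())
    becov = float(be_covered.mean())
    emp = d["empirical_se"]
    return MetricsRow(
        **d,
        model_se=model_se,
        model_se_mcse=float(np.sqrt(var_se2 / (4.0 * r * model_se**2)))
        if model_se > 0
        else np.nan,
        relative_error_model_se=100.0 * (model_se / emp - 1.0)
        if emp > 0
        else np.nan,
        coverage=cov,
        coverage_mcse=float(np.sqrt(cov * (1.0 - cov) / r)),
        bias_eliminated_coverage=becov,
        bias_eliminated_coverage_mcse=float(np.sqrt(becov * (1.0 - becov) / r)),
    )


def summarize_r2(
    r2: np.ndarray | pd.Series, true_value: float = 0.1
) -> MetricsRow:
    """Summarize per-replicate adjusted R^2 values (no per-rep SE, hence no
    model-SE or coverage fields)."""
    v = np.asarray(r2, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 replicates")
    bad = np.flatnonzero(~np.isfinite(v))
    if len(bad):
        raise ValueError(f"non-finite R^2 at replicate index {bad[0]}")
    return MetricsRow(**_basic(v, true_value))


def zipper_table(
    fits: pd.DataFrame, true_value: float, fraction: float = 0.5
) -> pd.DataFrame:
    """Ranked confidence-interval table for zipper plots.

    Computes z = (beta_hat - beta)/se per replicate, ranks by |z| descending
    and returns the top ``fraction`` of replicates with their fractional
    centile, 95% CI bounds and a covers-truth flag.  With ``fraction=1`` the
    mean of ``covers`` equals the coverage reported by
    :func:`summarize_estimates`.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    b = fits["beta_hat"].to_numpy(dtype=float)
    s = fits["se"].to_numpy(dtype=float)
    z = (b - true_value) / s
    order = np.argsort(-np.abs(z), kind="stable")
    k = max(1, int(round(fraction * len(b))))
    take = order[:k]
    n = len(b)
    out = pd.DataFrame(
        {
            "rep": fits["rep"].to_numpy()[take]
            if "rep" in fits.columns
            else take,
            "beta_hat": b[take],
            "se": s[take],
            "z": z[take],
            "centile": 100.0 * (np.arange(1, k + 1) - 0.5) / n,
            "ci_low": b[take] - Z95 * s[take],
            "ci_high": b[take] + Z95 * s[take],
        }
    )
    out["covers"] = (out["ci_low"] <= true_value) & (true_value <= out["ci_high"])
    return out
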