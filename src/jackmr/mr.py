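"""One-sample instrumental-variable estimation.

Univariable and multivariable (just-identified) two-stage least squares with
conventional homoskedastic model-based standard errors: the error variance is
estimated from second-stage residuals formed with the *observed* exposure,
``y - X @ beta_hat``, not the first-stage fitted exposure.  Confidence
intervals use the normal 1.96 multiplier (cohort sizes here are large).

First-stage diagnostics: adjusted R^2 of the exposure on the instrument, the
first-stage F-statistic, and (multivariable) a conditional F in the
Sanderson-Windmeijer spirit — the partial F of the instruments once the other
exposure's first-stage prediction is accounted for.

Also houses the rank-based inverse normal transformation (Blom offset 3/8)
used to normalize skewed traits before MR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import ScoreVector

__all__ = [
    "MrFit",
    "WeakInstrumentError",
    "tsls_fit",
    "tsls_multivariable",
    "first_stage_fstat",
    "adjusted_r2",
    "rank_inverse_normal",
    "write_fit_records",
]

Z95 = 1.96


class WeakInstrumentError(ValueError):
    """Raised when an instrument has (near-)zero variance, e.g. an empty PRS."""


@dataclass
class MrFit:
    """A 2SLS fit: estimate(s), model-based SE(s), CI, first-stage diagnostics.

    Scalar-valued in the univariable case; arrays of length 2 in the
    multivariable (two-exposure) case.  ``z`` is the standardized deviation
    from a supplied true effect, used by the simulation metrics.
    """

    beta_hat: float | np.ndarray
    se: float | np.ndarray
    ci_low: float | np.ndarray
    ci_high: float | np.ndarray
    fstat: float | np.ndarray
    r2_adj: float | np.ndarray
    n: int
    z: float | np.ndarray | None = None


def _as_values(instrument) -> np.ndarray:
    if isinstance(instrument, ScoreVector):
        return np.asarray(instrument.values, dtype=float)
    return np.asarray(instrument, dtype=float)


def _instrument_label(instrument) -> str:
    if isinstance(instrument, ScoreVector):
        return (
            f"{instrument.framework or 'instrument'} PRS at threshold "
            f"{instrument.threshold} ({instrument.n_snps_used} SNPs)"
        )
    return "instrument"


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Exogenous regressors: intercept plus optional covariate columns."""
    if covariates is None:
        return np.ones((n, 1))
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n:
        c = c.T
    if c.shape[0] != n:
        raise ValueError("covariate rows must match sample size")
    w = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(w) < w.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient covariate matrix")
    return w


def _residualize(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``a`` after OLS on ``w``."""
    coef, *_ = np.linalg.lstsq(w, a, rcond=None)
    return a - w @ coef


def adjusted_r2(exposure: np.ndarray, score) -> float:
    """Adjusted R^2 of the univariate regression of exposure on the score:
    1 - (1 - R^2) (n - 1)/(n - 2)."""
    x = np.asarray(exposure, dtype=float)
    z = _as_values(score)
    n = len(x)
    if n <= 2:
        raise ValueError("need n > 2 for adjusted R^2")
    xc = x - x.mean()
    zc = z - z.mean()
    szz = zc @ zc
    sxx = xc @ xc
    if szz <= 0.0 or sxx <= 0.0:
        raise WeakInstrumentError("zero-variance input to adjusted_r2")
    r2 = (zc @ xc) ** 2 / (szz * sxx)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def first_stage_fstat(
    exposure: np.ndarray, instrument, covariates: np.ndarray | None = None
) -> float:
    """First-stage F for the instrument block via nested-model RSS.

    F = ((RSS_restricted - RSS_full)/q) / (RSS_full/(n - k)); equals the
    squared first-stage t-statistic for a single instrument.  Overflow-guarded
    when the instrument reproduces the exposure exactly.
    """
    x = np.asarray(exposure, dtype=float)
    z = _as_values(instrument)
    if z.ndim == 1:
        z = z[:, None]
    n = len(x)
    w = _design(n, covariates)
    q = z.shape[1]
    full = np.column_stack([w, z])
    rss_r = float(np.sum(_residualize(x[:, None], w) ** 2))
    rss_f = float(np.sum(_residualize(x[:, None], full) ** 2))
    k = full.shape[1]
    if rss_f <= 0.0:
        return np.finfo(float).max
    return ((rss_r - rss_f) / q) / (rss_f / (n - k))


def tsls_fit(
    outcome: np.ndarray,
    exposure: np.ndarray,
    instrument,
    covariates: np.ndarray | None = None,
    true_value: float | None = None,
) -> MrFit:
    """Univariable one-sample 2SLS of outcome on exposure.

    With covariates W (always including an intercept) the estimate is the
    IV ratio on W-residualized variables, cov(Z~, Y~)/cov(Z~, X~).  The
    model-based SE uses sigma^2 = RSS/(n - k) with residuals from the
    observed exposure and k = number of second-stage regressors.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = _as_values(instrument)
    n = len(y)
    if len(x) != n or len(z) != n:
        raise ValueError("outcome, exposure and instrument lengths differ")
    w = _design(n, covariates)
    resid = _residualize(np.column_stack([y, x, z]), w)
    yt, xt, zt = resid[:, 0], resid[:, 1], resid[:, 2]
    szz = zt @ zt
    if szz <= 0.0 or not np.isfinite(szz):
        raise WeakInstrumentError(
            f"zero-variance instrument: {_instrument_label(instrument)}"
        )
    szx = zt @ xt
    if szx == 0.0:
        raise WeakInstrumentError(
            f"instrument uncorrelated with exposure: {_instrument_label(instrument)}"
        )
    beta = (zt @ yt) / szx
    # second-stage residuals with the OBSERVED exposure; W-coefs re-fit
    u = _residualize((y - beta * x)[:, None], w).ravel()
    k = w.shape[1] + 1
    sigma2 = (u @ u) / (n - k)
    # Var(beta) = sigma^2 * szz / szx^2  (projection of xt on zt)
    se = float(np.sqrt(sigma2 * szz / szx**2))
    fstat = first_stage_fstat(x, z, covariates)
    r2a = adjusted_r2(x, z) if covariates is None else adjusted_r2(
        xt + x.mean(), zt
    )
    return MrFit(
        beta_hat=float(beta),
        se=se,
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        fstat=float(fstat),
        r2_adj=float(r2a),
        n=n,
        z=None if true_value is None else float((beta - true_value) / se),
    )


def tsls_multivariable(
    outcome: np.ndarray,
    exposures: np.ndarray,
    instruments,
    covariates: np.ndarray | None = None,
    true_values: np.ndarray | None = None,
) -> MrFit:
    """Just-identified multivariable 2SLS with two exposures and two
    instruments; returns joint (direct) effects with conditional F-statistics.

    Estimates solve the moment equations Z'(y - X beta - W gamma) = 0.  The
    conditional F for exposure j is the partial F of both instruments in the
    first stage of exposure j after accounting for the other exposure's
    first-stage prediction.
    """
    y = np.asarray(outcome, dtype=float)
    if isinstance(exposures, (list, tuple)):
        x = np.column_stack([np.asarray(e, dtype=float) for e in exposures])
    else:
        x = np.asarray(exposures, dtype=float)
    if isinstance(instruments, (list, tuple)):
        z = np.column_stack([_as_values(i) for i in instruments])
    else:
        z = np.asarray(instruments, dtype=float)
    n = len(y)
    p = x.shape[1]
    if z.shape != (n, p):
        raise ValueError("need one instrument column per exposure (just-identified)")
    w = _design(n, covariates)
    yt = _residualize(y[:, None], w).ravel()
    xt = _residualize(x, w)
    zt = _residualize(z, w)
    zx = zt.T @ xt
    if np.linalg.matrix_rank(zx) < p:
        raise np.linalg.LinAlgError("collinear instruments: Z'X is rank-deficient")
    beta = np.linalg.solve(zx, zt.T @ yt)
    u = _residualize((y - x @ beta)[:, None], w).ravel()
    k = w.shape[1] + p
    sigma2 = (u @ u) / (n - k)
    zz = zt.T @ zt
    cov = sigma2 * np.linalg.solve(zx, np.linalg.solve(zx, zz).T)
    se = np.sqrt(np.diag(cov))

    # conditional F per exposure (Sanderson-Windmeijer-style partial F)
    fstats = np.empty(p)
    xhat = zt @ np.linalg.lstsq(zt, xt, rcond=None)[0]
    for j in range(p):
        others = xhat[:, [i for i in range(p) if i != j]]
        base = np.column_stack([w, others])
        full = np.column_stack([base, zt])
        rss_r = float(np.sum(_residualize(x[:, [j]], base) ** 2))
        rss_f = float(np.sum(_residualize(x[:, [j]], full) ** 2))
        q = p - (p - 1)  # instruments minus other exposures
        kf = np.linalg.matrix_rank(full)
        fstats[j] = (
            np.finfo(float).max
            if rss_f <= 0.0
            else ((rss_r - rss_f) / q) / (rss_f / (n - kf))
        )

    r2a = np.array([adjusted_r2(x[:, j], xhat[:, j]) for j in range(p)])
    zscores = (
        None
        if true_values is None
        else (beta - np.asarray(true_values, float)) / se
    )
    return MrFit(
        beta_hat=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        fstat=fstats,
        r2_adj=r2a,
        n=n,
        z=zscores,
    )


def rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transformation with Blom offset.

    Maps value with (average, tie-shared) rank r to
    Phi^{-1}((r - c)/(n - 2c + 1)).  Monotone; a constant vector is an error
    because every rank is tied.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == v[0]):
        raise ValueError("constant vector: all ranks tied")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def write_fit_records(records, path) -> None:
    """Delimited per-fit rows: the unit of exchange with the metrics module.

    ``records`` is an iterable of dicts with keys
    scenario framework threshold rep beta_hat se ci_low ci_high fstat r2_adj
    n_snps.
    """
    import pandas as pd

    pd.DataFrame(list(records)).to_csv(path, index=False, float_format="%.17g")
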