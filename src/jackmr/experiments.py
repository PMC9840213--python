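"""Scenario runner for the simulation studies.

Four studies are provided:

* ``run_primary_grid`` — three instrument frameworks x 13 P-value thresholds
  under the default generative parameters;
* ``run_external_size_sweep`` — external discovery GWAS of varying size
  against jackknife/overlap arms on a fixed applied cohort, at P<=5e-8;
* ``run_snp_sweep`` — varying SNP number at fixed total explained variance,
  thresholds {5e-8, 0.05, 1};
* ``run_block_sweep`` — varying jackknife block count, same three thresholds,
  with external and overlap reference arms.

Each replicate simulates fresh cohorts, rank-inverse-normalizes the outcome
(so MR estimates are expressed per SD of the outcome, mirroring how skewed
outcomes are handled in applied MR pipelines), performs ONE GWAS per
framework (per-block scans for the jackknife), and applies every threshold
as post-hoc filtering of that single scan — thresholding never re-runs a
regression.
Scores for all thresholds are assembled in a single matrix product, and the
univariable 2SLS fits are evaluated in closed form column-wise; the closed
form is tested to agree with :func:`jackmr.mr.tsls_fit` at machine precision.

Replicates draw from independent child streams of one root seed
(``numpy.random.SeedSequence.spawn``), so results are independent of
execution order and of the worker count when running with ``n_jobs > 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .frameworks import BlockAssignment, _block_suffstats, _loo_scans, assign_blocks
from .gwas import _scan_arrays
from .mr import Z95, rank_inverse_normal
from .simmetrics import summarize_estimates, summarize_r2
from .simulate import (
    SimulationParams,
    allocate_true_effects,
    simulate_cohort,
    write_params,
)

__all__ = [
    "ScenarioGrid",
    "run_primary_grid",
    "run_external_size_sweep",
    "run_snp_sweep",
    "run_block_sweep",
    "compute_metrics",
]

FRAMEWORKS = ("external", "overlap", "jackknife")

PER_REP_COLUMNS = [
    "scenario", "framework", "threshold", "rep", "n_snp", "n_block",
    "n_external", "r2_adj", "beta_hat", "se", "ci_low", "ci_high",
    "fstat", "n_snps",
]


@dataclass
class ScenarioGrid:
    """One simulation study: base parameters, varied axes, replicate count."""

    name: str
    base: SimulationParams
    reps: int
    axes: dict = field(default_factory=dict)
    frameworks: tuple[str, ...] = FRAMEWORKS
    out_dir: Path | None = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError("reps must be >= 2")
        bad = set(self.frameworks) - set(FRAMEWORKS)
        if bad:
            raise ValueError(f"unknown frameworks: {bad}")


# ---------------------------------------------------------------------------
# closed-form column-wise engine

def _scores_from_scan(
    g: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pval: np.ndarray,
    thresholds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Score matrix (n x T) and per-threshold SNP counts from one scan.

    Monomorphic SNPs (se=+inf) are excluded at every threshold, matching
    :func:`jackmr.scoring.select_snps`.
    """
    mask = (pval[:, None] <= thresholds[None, :]) & np.isfinite(se)[:, None]
    w = np.where(mask, beta[:, None], 0.0)
    return g @ w, mask.sum(axis=0)


def _iv_columns(
    x: np.ndarray, y: np.ndarray, scores: np.ndarray, n_snps: np.ndarray
) -> dict[str, np.ndarray]:
    """Adjusted R^2 and closed-form just-identified 2SLS per score column.

    Columns with an empty selection (zero-variance score) come back as NaN;
    they are recorded as NA rows and excluded from metrics with a count.
    """
    n = len(x)
    xt = x - x.mean()
    yt = y - y.mean()
    sxx = xt @ xt
    syy = yt @ yt
    sxy = xt @ yt
    sc = scores - scores.mean(axis=0)
    szz = np.einsum("ij,ij->j", sc, sc)
    szx = xt @ sc
    szy = yt @ sc
    valid = (n_snps > 0) & (szz > 0) & (szx != 0)
    szx_ = np.where(valid, szx, 1.0)
    szz_ = np.where(valid, szz, 1.0)
    beta = np.where(valid, szy / szx_, np.nan)
    rss = syy - 2.0 * beta * sxy + beta**2 * sxx
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * szz_ / szx_**2)
    denom = szz_ * sxx - szx_**2
    fstat = np.where(valid, (n - 2) * szx_**2 / denom, np.nan)
    r2 = np.where(valid, szx_**2 / (szz_ * sxx), np.nan)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {
        "r2_adj": r2_adj,
        "beta_hat": np.where(valid, beta, np.nan),
        "se": np.where(valid, se, np.nan),
        "fstat": fstat,
    }


def _jackknife_scores(
    g: np.ndarray,
    exposure: np.ndarray,
    blocks: BlockAssignment,
    thresholds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Assembled cross-fitted score matrix (n x T) and per-threshold counts of
    distinct SNPs used in any block."""
    ss = _block_suffstats(g, exposure, blocks)
    scans = _loo_scans(ss)
    n, m = g.shape
    scores = np.zeros((n, len(thresholds)))
    used = np.zeros((m, len(thresholds)), dtype=bool)
    for b in range(1, blocks.n_block + 1):
        beta, se, pval, _ = scans[b - 1]
        mask = (pval[:, None] <= thresholds[None, :]) & np.isfinite(se)[:, None]
        w = np.where(mask, beta[:, None], 0.0)
        idx = blocks.indices(b)
        scores[idx] = g[idx] @ w
        used |= mask
    return scores, used.sum(axis=0)


def _rows(
    scenario: str,
    framework: str,
    thresholds: np.ndarray,
    rep: int,
    params: SimulationParams,
    stats: dict[str, np.ndarray],
    n_snps: np.ndarray,
    n_external: float,
    n_block: float,
) -> list[dict]:
    out = []
    for t in range(len(thresholds)):
        beta = stats["beta_hat"][t]
        se = stats["se"][t]
        out.append(
            {
                "scenario": scenario,
                "framework": framework,
                "threshold": thresholds[t],
                "rep": rep,
                "n_snp": params.n_snp,
                "n_block": n_block,
                "n_external": n_external,
                "r2_adj": stats["r2_adj"][t],
                "beta_hat": beta,
                "se": se,
                "ci_low": beta - Z95 * se,
                "ci_high": beta + Z95 * se,
                "fstat": stats["fstat"][t],
                "n_snps": int(n_snps[t]),
            }
        )
    return out


def _rep_standard(
    params: SimulationParams,
    rng: np.random.Generator,
    frameworks: tuple[str, ...],
    scenario: str,
    rep: int,
    n_block_list: tuple[int, ...] | None = None,
) -> list[dict]:
    """One replicate of the primary-style grid (optionally several block
    counts for the jackknife arm)."""
    thresholds = np.asarray(params.thresholds, dtype=float)
    effects = allocate_true_effects(params, rng)
    applied = simulate_cohort(params, effects, "applied", rng)
    need_external = "external" in frameworks
    external = (
        simulate_cohort(params, effects, "external", rng) if need_external else None
    )
    ga, x = applied.genotypes, applied.exposure
    # outcome is rank-inverse-normalized before MR (see module docstring)
    y = rank_inverse_normal(applied.outcome)
    rows: list[dict] = []
    if need_external:
        beta, se, pval = _scan_arrays(external.genotypes, external.exposure)
        s, k = _scores_from_scan(ga, beta, se, pval, thresholds)
        rows += _rows(scenario, "external", thresholds, rep, params,
                      _iv_columns(x, y, s, k), k, params.n_external, np.nan)
    if "overlap" in frameworks:
        beta, se, pval = _scan_arrays(ga, x)
        s, k = _scores_from_scan(ga, beta, se, pval, thresholds)
        rows += _rows(scenario, "overlap", thresholds, rep, params,
                      _iv_columns(x, y, s, k), k, np.nan, np.nan)
    if "jackknife" in frameworks:
        for nb in n_block_list or (params.n_block,):
            blocks = assign_blocks(applied.n, nb, rng)
            s, k = _jackknife_scores(ga, x, blocks, thresholds)
            rows += _rows(scenario, "jackknife", thresholds, rep, params,
                          _iv_columns(x, y, s, k), k, np.nan, nb)
    return rows


def _rep_size_sweep(
    params: SimulationParams,
    rng: np.random.Generator,
    frameworks: tuple[str, ...],
    n_ext_list: tuple[int, ...],
    scenario: str,
    rep: int,
) -> list[dict]:
    """One replicate of the external-size sweep: one applied cohort shared by
    all arms; a fresh external cohort per external sample size."""
    thresholds = np.asarray(params.thresholds, dtype=float)
    effects = allocate_true_effects(params, rng)
    applied = simulate_cohort(params, effects, "applied", rng)
    ga, x = applied.genotypes, applied.exposure
    y = rank_inverse_normal(applied.outcome)
    rows: list[dict] = []
    if "overlap" in frameworks:
        beta, se, pval = _scan_arrays(ga, x)
        s, k = _scores_from_scan(ga, beta, se, pval, thresholds)
        rows += _rows(scenario, "overlap", thresholds, rep, params,
                      _iv_columns(x, y, s, k), k, np.nan, np.nan)
    if "jackknife" in frameworks:
        blocks = assign_blocks(applied.n, params.n_block, rng)
        s, k = _jackknife_scores(ga, x, blocks, thresholds)
        rows += _rows(scenario, "jackknife", thresholds, rep, params,
                      _iv_columns(x, y, s, k), k, np.nan, params.n_block)
    if "external" in frameworks:
        for n_ext in n_ext_list:
            ext = simulate_cohort(params, effects, "external", rng, n=n_ext)
            beta, se, pval = _scan_arrays(ext.genotypes, ext.exposure)
            s, k = _scores_from_scan(ga, beta, se, pval, thresholds)
            rows += _rows(scenario, "external", thresholds, rep, params,
                          _iv_columns(x, y, s, k), k, n_ext, np.nan)
    return rows


def _run_reps(grid: ScenarioGrid, rep_fn, seed: int | None) -> pd.DataFrame:
    root = grid.base.seed if seed is None else seed
    children = np.random.SeedSequence(root).spawn(grid.reps)
    def one(i):
        rng = np.random.default_rng(children[i])
        return rep_fn(i, rng)
    if grid.n_jobs and grid.n_jobs != 1:
        chunks = Parallel(n_jobs=grid.n_jobs)(
            delayed(one)(i) for i in range(grid.reps)
        )
    else:
        chunks = [one(i) for i in range(grid.reps)]
    rows = [r for chunk in chunks for r in chunk]
    return pd.DataFrame(rows, columns=PER_REP_COLUMNS)


def compute_metrics(
    per_rep: pd.DataFrame,
    true_beta: float,
    true_r2: float,
) -> pd.DataFrame:
    """Per-cell Monte-Carlo summaries of beta_hat (with coverage) and
    adjusted R^2, plus the precision gain versus the external arm.

    Replicates whose instrument was empty (NA rows) are excluded with a
    reported ``n_excluded`` count rather than silently dropped.
    """
    keys = ["scenario", "framework", "threshold", "n_snp", "n_block", "n_external"]
    df = per_rep.copy()
    for k in ("n_block", "n_external"):
        df[k] = df[k].fillna(-1)
    out = []
    for key_vals, sub in df.groupby(keys, dropna=False, sort=True):
        ok = sub[np.isfinite(sub["beta_hat"]) & np.isfinite(sub["se"])]
        rec = dict(zip(keys, key_vals))
        rec["n_excluded"] = len(sub) - len(ok)
        if len(ok) >= 2:
            mb = summarize_estimates(ok, true_value=true_beta)
            for f, v in mb.to_dict().items():
                rec[f"beta_{f}"] = v
            mr2 = summarize_r2(ok["r2_adj"], true_value=true_r2)
            for f, v in mr2.to_dict().items():
                if not (isinstance(v, float) and np.isnan(v)):
                    rec[f"r2_{f}"] = v
        out.append(rec)
    metrics = pd.DataFrame(out)
    # precision gain relative to the external arm in the same cell
    if "external" in set(metrics["framework"]):
        cell = ["scenario", "threshold", "n_snp"]
        ext = (
            metrics[metrics["framework"] == "external"]
            .groupby(cell)["beta_empirical_se"]
            .mean()
        )
        gains = []
        for _, row in metrics.iterrows():
            key = tuple(row[c] for c in cell)
            ref = ext.get(key, np.nan)
            emp = row.get("beta_empirical_se", np.nan)
            gains.append(
                100.0 * ((ref / emp) ** 2 - 1.0)
                if np.isfinite(ref) and np.isfinite(emp) and emp > 0
                else np.nan
            )
        metrics["beta_precision_gain_vs_external"] = gains
    for k in ("n_block", "n_external"):
        metrics[k] = metrics[k].replace(-1, np.nan)
    return metrics


def _finalize(
    grid: ScenarioGrid, per_rep: pd.DataFrame, seed: int | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    metrics = compute_metrics(
        per_rep, true_beta=grid.base.beta_xy, true_r2=grid.base.var_exp
    )
    if grid.out_dir is not None:
        out = Path(grid.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_rep.to_csv(out / "per_rep.csv", index=False, float_format="%.17g")
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.17g")
        write_params(
            grid.base, out / "config.yaml",
            scenario=grid.name, reps=grid.reps,
            resolved_seed=grid.base.seed if seed is None else seed,
            axes={k: list(v) for k, v in grid.axes.items()},
            frameworks=list(grid.frameworks),
        )
    return per_rep, metrics


def run_primary_grid(
    grid: ScenarioGrid, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three frameworks x the threshold grid under the base parameters."""
    per_rep = _run_reps(
        grid,
        lambda i, rng: _rep_standard(grid.base, rng, grid.frameworks, grid.name, i),
        seed,
    )
    return _finalize(grid, per_rep, seed)


def run_external_size_sweep(
    grid: ScenarioGrid, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """External arm at each n_external in ``grid.axes['n_external']``;
    jackknife/overlap arms once per replicate on the applied cohort."""
    n_ext_list = tuple(grid.axes.get("n_external", (grid.base.n_external,)))
    per_rep = _run_reps(
        grid,
        lambda i, rng: _rep_size_sweep(
            grid.base, rng, grid.frameworks, n_ext_list, grid.name, i
        ),
        seed,
    )
    return _finalize(grid, per_rep, seed)


def run_snp_sweep(
    grid: ScenarioGrid, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primary-style grid repeated for each n_snp in ``grid.axes['n_snp']``
    (total explained variance held fixed)."""
    n_snp_list = tuple(grid.axes.get("n_snp", (grid.base.n_snp,)))

    def rep_fn(i, rng):
        rows = []
        for m in n_snp_list:
            params = grid.base.with_(n_snp=m)
            rows += _rep_standard(params, rng, grid.frameworks, grid.name, i)
        return rows

    per_rep = _run_reps(grid, rep_fn, seed)
    return _finalize(grid, per_rep, seed)


def run_block_sweep(
    grid: ScenarioGrid, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Jackknife arm across block counts with external/overlap references."""
    n_block_list = tuple(grid.axes.get("n_block", (grid.base.n_block,)))
    per_rep = _run_reps(
        grid,
        lambda i, rng: _rep_standard(
            grid.base, rng, grid.frameworks, grid.name, i,
            n_block_list=n_block_list,
        ),
        seed,
    )
    return _finalize(grid, per_rep, seed)
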