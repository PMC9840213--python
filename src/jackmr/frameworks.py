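"""The three instrument-construction frameworks for one-sample MR.

* ``external_prs`` — discovery GWAS on an independent cohort; the applied
  cohort only contributes dosages to the score (no sample overlap).
* ``overlap_prs`` — discovery GWAS on the applied cohort itself (100%
  overlap); subject to winner's-curse / overfitting bias.
* ``jackknife_prs`` — the cross-fitted design: the applied cohort is split
  into ``n_block`` balanced blocks; each block is scored with weights from a
  GWAS on the other blocks, so no individual's data ever enters the scan
  that produced their own weights.

The leave-one-block-out scans are computed by subtracting per-block column
sums from full-cohort sums, so the jackknife costs one extra pass over the
genotype matrix rather than ``n_block`` full scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import _scan_stats, gwas_scan
from .scoring import PrsWeights, ScoreVector, compute_prs, select_snps
from .simulate import Cohort

__all__ = [
    "BlockAssignment",
    "assign_blocks",
    "external_prs",
    "overlap_prs",
    "jackknife_prs",
    "write_blocks",
    "read_blocks",
]


@dataclass
class BlockAssignment:
    """A balanced random partition of 1..n individuals into blocks.

    ``block_of[i]`` is the 1-based block label of individual i; block sizes
    differ by at most one.
    """

    block_of: np.ndarray
    n_block: int

    @property
    def n(self) -> int:
        return len(self.block_of)

    def indices(self, block: int) -> np.ndarray:
        """Row indices of the given (1-based) block."""
        return np.flatnonzero(self.block_of == block)


def assign_blocks(n: int, n_block: int, rng: np.random.Generator) -> BlockAssignment:
    """Uniformly random balanced partition of n individuals into n_block blocks."""
    if n_block < 2:
        raise ValueError(f"n_block must be >= 2, got {n_block}")
    if n < n_block:
        raise ValueError(f"cannot split {n} individuals into {n_block} blocks")
    labels = np.repeat(np.arange(1, n_block + 1), np.diff(
        np.linspace(0, n, n_block + 1).astype(int)
    ))
    return BlockAssignment(block_of=rng.permutation(labels), n_block=n_block)


def external_prs(applied: Cohort, external: Cohort, threshold: float) -> ScoreVector:
    """Externally weighted score: scan the external cohort's exposure, select
    at the threshold, score the applied cohort's dosages."""
    if applied.n_snp != external.n_snp:
        raise ValueError("applied and external cohorts must share the SNP set")
    scan = gwas_scan(external.genotypes, external.exposure)
    weights = select_snps(scan, threshold, source="external")
    score = compute_prs(applied.genotypes, weights)
    score.framework = "external"
    return score


def overlap_prs(applied: Cohort, threshold: float) -> ScoreVector:
    """Fully overlapping score: discovery and scoring on the same cohort."""
    scan = gwas_scan(applied.genotypes, applied.exposure)
    weights = select_snps(scan, threshold, source="overlap")
    score = compute_prs(applied.genotypes, weights)
    score.framework = "overlap"
    return score


def _block_suffstats(
    g: np.ndarray, y: np.ndarray, blocks: BlockAssignment
) -> dict[str, np.ndarray]:
    """Per-block and total column sums feeding the leave-one-block-out scans."""
    n, m = g.shape
    nb = blocks.n_block
    s_g = np.empty((nb, m))
    s_gg = np.empty((nb, m))
    s_gy = np.empty((nb, m))
    s_y = np.empty(nb)
    s_yy = np.empty(nb)
    sizes = np.empty(nb, dtype=int)
    for b in range(1, nb + 1):
        idx = blocks.indices(b)
        gb = g[idx]
        yb = y[idx]
        s_g[b - 1] = gb.sum(axis=0)
        s_gg[b - 1] = np.einsum("ij,ij->j", gb, gb)
        s_gy[b - 1] = yb @ gb
        s_y[b - 1] = yb.sum()
        s_yy[b - 1] = yb @ yb
        sizes[b - 1] = len(idx)
    return {
        "s_g": s_g, "s_gg": s_gg, "s_gy": s_gy,
        "s_y": s_y, "s_yy": s_yy, "sizes": sizes,
    }


def _loo_scans(ss: dict[str, np.ndarray]) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, int]]:
    """Leave-one-block-out scan statistics: for each block b, the scan of the
    exposure on all individuals NOT in b.  Returns (beta, se, pvalue, n_disc)
    per block."""
    tot_g = ss["s_g"].sum(axis=0)
    tot_gg = ss["s_gg"].sum(axis=0)
    tot_gy = ss["s_gy"].sum(axis=0)
    tot_y = ss["s_y"].sum()
    tot_yy = ss["s_yy"].sum()
    n = int(ss["sizes"].sum())
    out = []
    for b in range(len(ss["sizes"])):
        n_disc = n - int(ss["sizes"][b])
        if n_disc < 3:
            raise ValueError(
                "leave-one-block-out scan would have fewer than 3 individuals"
            )
        beta, se, pval = _scan_stats(
            tot_g - ss["s_g"][b],
            tot_gg - ss["s_gg"][b],
            tot_gy - ss["s_gy"][b],
            tot_y - ss["s_y"][b],
            tot_yy - ss["s_yy"][b],
            n_disc,
        )
        out.append((beta, se, pval, n_disc))
    return out


def jackknife_prs(
    applied: Cohort,
    n_block: int,
    threshold: float,
    rng: np.random.Generator,
    blocks: BlockAssignment | None = None,
) -> tuple[ScoreVector, list[PrsWeights], BlockAssignment]:
    """Block jackknife resampled score.

    For each block b: scan the exposure on all individuals not in b, select
    SNPs at the threshold, and score the members of b with those weights.
    Per-block SNP sets and weights legitimately differ, so the assembled
    score is heterogeneous across blocks by design.  A pre-computed
    ``blocks`` assignment may be supplied (e.g. to reuse one partition
    across phenotypes); otherwise one is drawn from ``rng``.
    """
    if blocks is None:
        blocks = assign_blocks(applied.n, n_block, rng)
    elif blocks.n != applied.n or blocks.n_block != n_block:
        raise ValueError("supplied block assignment does not match cohort/n_block")
    g = applied.genotypes
    ss = _block_suffstats(g, applied.exposure, blocks)
    scans = _loo_scans(ss)
    values = np.zeros(applied.n)
    per_block_weights: list[PrsWeights] = []
    used: set[int] = set()
    for b in range(1, n_block + 1):
        beta, se, pval, n_disc = scans[b - 1]
        sel = pval <= threshold
        ids = np.flatnonzero(sel)
        w = PrsWeights(
            threshold=threshold,
            entries=dict(zip((int(i) for i in ids), beta[sel].tolist())),
            source=f"jackknife-block-{b}",
        )
        per_block_weights.append(w)
        idx = blocks.indices(b)
        if len(ids):
            values[idx] = g[np.ix_(idx, ids)] @ beta[sel]
            used.update(int(i) for i in ids)
    score = ScoreVector(
        values=values,
        n_snps_used=len(used),
        threshold=threshold,
        framework="jackknife",
    )
    return score, per_block_weights, blocks


def write_blocks(blocks: BlockAssignment, path) -> None:
    pd.DataFrame(
        {"sample_id": np.arange(blocks.n), "block": blocks.block_of}
    ).to_csv(path, sep="\t", index=False)


def read_blocks(path) -> BlockAssignment:
    df = pd.read_csv(path, sep="\t")
    block_of = df["block"].to_numpy(dtype=int)
    return BlockAssignment(block_of=block_of, n_block=int(block_of.max()))
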