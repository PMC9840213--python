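"""Threshold-based SNP selection and weighted allele-score construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrsWeights",
    "ScoreVector",
    "select_snps",
    "compute_prs",
    "write_weights",
    "read_weights",
    "write_scores",
    "read_scores",
]


@dataclass
class PrsWeights:
    """SNPs passing a P-value cutoff with their discovery-beta weights.

    ``entries`` maps snp_id -> weight in genotype-column order; ``source``
    labels the discovery framework (``external``, ``overlap`` or
    ``jackknife-block-<b>``).
    """

    threshold: float
    entries: dict[int, float]
    source: str = ""

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ScoreVector:
    """Per-individual weighted allele score at one threshold."""

    values: np.ndarray
    n_snps_used: int
    threshold: float
    framework: str = ""


def select_snps(gwas: pd.DataFrame, threshold: float, source: str = "") -> PrsWeights:
    """Select SNPs with discovery P <= threshold; weight = discovery beta.

    The comparison is inclusive and order-preserving; an empty selection is a
    legal result (downstream 2SLS raises on the resulting zero-variance
    score).  Monomorphic SNPs (reported with se=+inf) are never selected,
    even at threshold 1.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    mask = (gwas["pvalue"].to_numpy() <= threshold) & np.isfinite(
        gwas["se"].to_numpy()
    )
    ids = gwas["snp_id"].to_numpy()[mask]
    betas = gwas["beta_hat"].to_numpy()[mask]
    return PrsWeights(
        threshold=threshold,
        entries=dict(zip((int(i) for i in ids), (float(b) for b in betas))),
        source=source,
    )


def compute_prs(genotypes: np.ndarray, weights: PrsWeights) -> ScoreVector:
    """Weighted sum of effect-allele dosages over the selected SNPs.

    score_i = sum_j w_j * dosage_ij.  Empty weights give an all-zero score
    with ``n_snps_used = 0``; an snp_id outside the genotype columns is a
    hard error (it signals weight/genotype misalignment).
    """
    g = np.asarray(genotypes, dtype=np.float64)
    n, m = g.shape
    if not weights.entries:
        return ScoreVector(
            values=np.zeros(n), n_snps_used=0,
            threshold=weights.threshold, framework=weights.source,
        )
    idx = np.fromiter(weights.entries.keys(), dtype=np.int64)
    w = np.fromiter(weights.entries.values(), dtype=np.float64)
    if idx.min() < 0 or idx.max() >= m:
        bad = idx[(idx < 0) | (idx >= m)]
        raise KeyError(
            f"snp_id(s) {bad.tolist()} not present in genotype matrix with "
            f"{m} SNPs"
        )
    values = g[:, idx] @ w
    return ScoreVector(
        values=values, n_snps_used=len(idx),
        threshold=weights.threshold, framework=weights.source,
    )


# file formats: weights `snp_id weight pvalue`, scores `sample_id score`

def write_weights(weights: PrsWeights, gwas: pd.DataFrame | None, path) -> None:
    ids = list(weights.entries)
    pv = (
        gwas.set_index("snp_id")["pvalue"].reindex(ids).to_numpy()
        if gwas is not None
        else np.full(len(ids), np.nan)
    )
    pd.DataFrame(
        {"snp_id": ids, "weight": list(weights.entries.values()), "pvalue": pv}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path, threshold: float = 1.0, source: str = "") -> PrsWeights:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return PrsWeights(
        threshold=threshold,
        entries=dict(zip(df["snp_id"].astype(int), df["weight"].astype(float))),
        source=source,
    )


def write_scores(score: ScoreVector, path) -> None:
    pd.DataFrame(
        {"sample_id": np.arange(len(score.values)), "score": score.values}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores(path, threshold: float = 1.0, framework: str = "") -> ScoreVector:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    v = df["score"].to_numpy(dtype=float)
    # the file does not record how many SNPs contributed
    return ScoreVector(
        values=v, n_snps_used=0, threshold=threshold, framework=framework
    )
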