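"""Principal component analysis of genotype matrices.

Sites are standardized the way population-genetic PCA expects: missing
calls are replaced by the site mean, values are centered, and each site is
divided by ``sqrt(p(1-p))`` where ``p`` is a shrunk allele-frequency
estimate (Patterson scaling), so drifted rare variants do not dominate.
Components come from a dense eigendecomposition of the sample-sample
covariance; score columns are normalized to unit length, which means
absolute score magnitudes depend on sample size and are only comparable
within one analysis.

Eigenvector signs are arbitrary, so each component is oriented to make the
mean score of a designated anchor population non-negative — without this,
"extreme value" reporting downstream would not be deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["PCResult", "standardize", "compute_pcs", "project_samples"]


@dataclass
class PCResult:
    """Scores and spectra for the top K components."""

    sample_ids: list[str]
    populations: list[str]
    scores: np.ndarray  # (n_samples, K), unit-norm columns
    eigenvalues: np.ndarray  # (K,), non-increasing
    variance_explained: np.ndarray  # (K,), fractions of total variance
    snp_weights: np.ndarray | None = None  # (n_snps, K)
    sign_anchor: str | None = None
    projected: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    site_means: np.ndarray | None = None  # fit-time per-site means (for projection)
    site_scales: np.ndarray | None = None  # fit-time per-site Patterson scales

    def __post_init__(self):
        if self.projected.size == 0:
            self.projected = np.zeros(len(self.sample_ids), dtype=bool)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite PC scores")

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.k)]
        )
        df.insert(0, "population", self.populations)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def standardize(matrix: GenotypeMatrix) -> np.ndarray:
    """Mean-impute, center and Patterson-scale the call matrix.

    Every site must have at least two non-missing calls and nonzero MAF;
    monomorphic or empty sites make the scaling degenerate and indicate QC
    was skipped.
    """
    return _standardize_with_stats(matrix)[0]


def _standardize_with_stats(
    matrix: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    calls = matrix.calls.astype(float)
    obs = matrix.calls != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, calls, 0.0).sum(axis=0)
    if np.any(n_obs < 2):
        j = int(np.argmax(n_obs < 2))
        raise ValueError(
            f"site {matrix.snps[j].snp_id} has fewer than 2 non-missing calls; "
            "run QC before PCA"
        )
    mean = alt / n_obs
    if np.any(mean <= 0) or np.any(mean >= 2):
        j = int(np.argmax((mean <= 0) | (mean >= 2)))
        raise ValueError(
            f"site {matrix.snps[j].snp_id} is monomorphic; run QC before PCA"
        )
    # shrunk frequency estimate: posterior mean with a uniform prior
    p_shrunk = (alt + 1.0) / (2.0 * n_obs + 2.0)
    denom = np.sqrt(p_shrunk * (1.0 - p_shrunk))
    X = np.where(obs, calls, mean[None, :])  # mean imputation
    return (X - mean[None, :]) / denom[None, :], mean, denom


def _orient_signs(
    scores: np.ndarray, populations: list[str], anchor: str | None
) -> tuple[np.ndarray, str]:
    pops = sorted(set(populations))
    if anchor is None:
        anchor = pops[0]
    if anchor not in pops:
        raise ValueError(f"sign anchor population {anchor!r} not present")
    rows = np.asarray([i for i, p in enumerate(populations) if p == anchor])
    means = scores[rows].mean(axis=0)
    flip = np.where(means < 0, -1.0, 1.0)
    return scores * flip[None, :], anchor


def compute_pcs(
    matrix: GenotypeMatrix,
    k: int = 20,
    sign_anchor_population: str | None = None,
    keep_snp_weights: bool = True,
) -> PCResult:
    """Top-``k`` principal components of the standardized genotype matrix.

    Scores are the unit-norm eigenvectors of the sample-sample covariance
    ``X X^T / n_snps``; all samples are co-fitted (projection of held-out
    samples is a separate step, :func:`project_samples`).
    """
    n = matrix.n_samples
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n - 1}")
    X, site_means, site_scales = _standardize_with_stats(matrix)
    gram = (X @ X.T) / matrix.n_snps
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:k]
    eigenvalues = np.maximum(evals[order], 0.0)
    scores = evecs[:, order]
    scores, anchor = _orient_signs(scores, matrix.populations, sign_anchor_population)
    total_var = float(np.trace(gram))
    weights = None
    if keep_snp_weights:
        with np.errstate(invalid="ignore", divide="ignore"):
            # X ~ U S V^T with U = scores; columns of V scaled by singular value
            sv = np.sqrt(np.maximum(eigenvalues * matrix.n_snps, 1e-300))
            weights = (X.T @ scores)  # = V * S
            weights = weights / sv[None, :]  # V (unit columns)
    return PCResult(
        sample_ids=matrix.sample_ids,
        populations=matrix.populations,
        scores=scores,
        eigenvalues=eigenvalues,
        variance_explained=eigenvalues / total_var if total_var > 0 else eigenvalues,
        snp_weights=weights,
        sign_anchor=anchor,
        site_means=site_means,
        site_scales=site_scales,
    )


def project_samples(
    pc_result: PCResult, matrix: GenotypeMatrix, sample_ids: list[str]
) -> PCResult:
    """Least-squares projection of held-out samples onto fitted axes.

    Each sample's score is solved from its non-missing sites only, against
    the fitted SNP loadings (the aDNA "lsqproject" approach, which avoids
    the shrinkage toward zero that naive projection of sparse samples
    shows).  The samples must not have been part of the fit, and the
    matrix must contain the same SNPs the axes were fitted on.
    """
    if pc_result.snp_weights is None:
        raise ValueError("PCResult carries no SNP weights; refit with keep_snp_weights")
    fitted = set(pc_result.sample_ids)
    overlap = fitted & set(sample_ids)
    if overlap:
        raise ValueError(f"samples already in the fit set: {sorted(overlap)}")
    if matrix.n_snps != pc_result.snp_weights.shape[0]:
        raise ValueError("matrix SNP count does not match fitted loadings")
    index = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    missing = [s for s in sample_ids if s not in index]
    if missing:
        raise KeyError(f"unknown sample ids: {missing}")
    V = pc_result.snp_weights  # (n_snps, K), unit columns
    sv = np.sqrt(np.maximum(pc_result.eigenvalues * V.shape[0], 1e-300))
    if pc_result.site_means is None or pc_result.site_scales is None:
        raise ValueError("PCResult carries no fit-time standardization statistics")
    mean, denom = pc_result.site_means, pc_result.site_scales
    scores = np.zeros((len(sample_ids), pc_result.k))
    for out_i, sid in enumerate(sample_ids):
        row = matrix.calls[index[sid]].astype(float)
        obs = row != MISSING
        if not obs.any():
            raise ValueError(f"sample {sid} shares no SNPs with the fitted axes")
        x = (row[obs] - mean[obs]) / denom[obs]
        A = V[obs] * sv[None, :]  # model: x_obs ~ A @ u
        u, *_ = np.linalg.lstsq(A, x, rcond=None)
        scores[out_i] = u
    populations = [matrix.samples[index[s]].population for s in sample_ids]
    return PCResult(
        sample_ids=list(sample_ids),
        populations=populations,
        scores=scores,
        eigenvalues=pc_result.eigenvalues.copy(),
        variance_explained=pc_result.variance_explained.copy(),
        snp_weights=None,
        sign_anchor=pc_result.sign_anchor,
        projected=np.ones(len(sample_ids), dtype=bool),
    )
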