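"""f-statistics and simplified qpAdm/qpWave admixture modeling.

This is a self-contained re-implementation of the f4-statistic machinery
used for ancestry-proportion estimation, not a port of AdmixTools:

* ``f4(A, B; C, D)`` is the mean over usable SNPs of
  ``(p_A - p_B)(p_C - p_D)``, with a delete-one block jackknife over
  consecutive-SNP blocks for standard errors (linkage makes per-SNP values
  dependent; blocks restore approximate independence).
* The qpAdm-style fit writes the target as a mixture of sources in the
  space of f4-statistics against a panel of "right" (outgroup)
  populations.  With weights constrained to sum to one, the residual for
  right population ``R_j`` is ``sum_s a_s f4(T, S_s; R_j, R_0)``; weights
  minimize the generalized least-squares norm of this residual under the
  block-jackknife covariance, and the minimized chi-square yields the fit
  p-value with ``(|right| - 1) - (|sources| - 1)`` degrees of freedom.
* The qpWave-style rank test asks whether the matrix
  ``f4(L_i, L_0; R_j, R_0)`` is consistent with a given rank — i.e. how
  many independent ancestry streams relate the left populations to the
  right panel — via a GLS likelihood-ratio against the jackknife
  covariance, with a chi-square reference.

Frequency-based (not genotype-projection) f-statistics are used
throughout: adequate for simulated data and clearly documented as a
simplification; numerical agreement with AdmixTools on empirical data is
not promised.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._rand import child_rng
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "FStatResult",
    "AdmixtureFit",
    "ModelScanResult",
    "pop_allele_freqs",
    "f2",
    "f3",
    "f4",
    "qpwave_rank_test",
    "qpadm_fit",
    "model_scan",
    "block_bootstrap_ci",
]


@dataclass(frozen=True)
class FStatResult:
    stat_type: str
    populations: tuple[str, ...]
    value: float
    se: float
    z: float
    n_blocks: int
    n_snps: int


@dataclass
class AdmixtureFit:
    """qpAdm-style ancestry weights for one target/source configuration."""

    target: str
    sources: tuple[str, ...]
    weights: np.ndarray  # sum to 1
    weight_se: np.ndarray
    p_value: float
    feasible: bool  # all weights in [0, 1]
    dof: int
    n_blocks: int
    bootstrap_ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        assert abs(float(np.sum(self.weights)) - 1.0) < 1e-9

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, w, se in zip(self.sources, self.weights, self.weight_se):
            ci = self.bootstrap_ci.get(s) if self.bootstrap_ci else (np.nan, np.nan)
            rows.append(
                {
                    "source": s,
                    "weight": float(w),
                    "se": float(se),
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p_fit": self.p_value,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ModelScanResult:
    """All evaluated source subsets plus the accepted/selected models."""

    target: str
    evaluated: list[AdmixtureFit]
    failures: list[tuple[tuple[str, ...], str]]  # (sources, reason)
    p_threshold: float
    accepted: list[AdmixtureFit] = field(default_factory=list)
    selected: AdmixtureFit | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "sources": ",".join(f.sources),
                "k": len(f.sources),
                "p_value": f.p_value,
                "feasible": f.feasible,
                "accepted": f in self.accepted,
            }
            for f in self.evaluated
        ]
        rows += [
            {"sources": ",".join(s), "k": len(s), "p_value": np.nan,
             "feasible": False, "accepted": False}
            for s, _ in self.failures
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele frequencies and blocks
# ---------------------------------------------------------------------------

def pop_allele_freqs(
    matrix: GenotypeMatrix, populations: list[str]
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-population alt-allele frequency and call count at every SNP.

    Returns ``(freqs, counts)`` keyed by population label; sites with zero
    calls in a population have frequency NaN there, and joint statistics
    mask any site that is NaN in any participating population.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    index = matrix.population_index()
    unknown = sorted(set(populations) - set(index))
    if unknown:
        raise KeyError(f"unknown populations: {unknown}")
    freqs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for pop in dict.fromkeys(populations):  # preserve order, drop dups
        calls = matrix.calls[index[pop]]
        obs = calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(n > 0, alt / (2.0 * n), np.nan)
        counts[pop] = n
    return freqs, counts


def _block_slices(n_snps: int, block_size: int) -> list[slice]:
    return [slice(i, min(i + block_size, n_snps)) for i in range(0, n_snps, block_size)]


def _block_means(values: np.ndarray, block_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block nanmeans and usable-SNP counts; empty blocks are dropped.

    ``values`` may be 1-D (one statistic) or 2-D (n_snps, q) sharing one
    usable-site mask (NaN rows are jointly masked).
    """
    vals = values if values.ndim == 2 else values[:, None]
    usable = ~np.isnan(vals).any(axis=1)
    means, counts = [], []
    for sl in _block_slices(vals.shape[0], block_size):
        m = usable[sl]
        c = int(m.sum())
        if c == 0:
            continue
        means.append(vals[sl][m].mean(axis=0))
        counts.append(c)
    if not means:
        raise ValueError("no usable SNPs in any block")
    return np.asarray(means), np.asarray(counts, dtype=float)


def _jackknife_scalar(block_means: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Weighted overall mean and delete-one block jackknife SE."""
    n = counts.sum()
    total = float((block_means * counts).sum())
    theta = total / n
    B = block_means.size
    if B < 2:
        raise ValueError("need at least 2 usable blocks for the jackknife")
    loo = (total - block_means * counts) / (n - counts)
    se = np.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum())
    return theta, float(se)


def _jackknife_cov(block_vecs: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Delete-one block jackknife covariance of a weighted mean vector."""
    n = counts.sum()
    total = (block_vecs * counts[:, None]).sum(axis=0)
    loo = (total[None, :] - block_vecs * counts[:, None]) / (n - counts)[:, None]
    B = block_vecs.shape[0]
    centered = loo - loo.mean(axis=0, keepdims=True)
    return (B - 1) / B * (centered.T @ centered)


def _fstat(
    stat_type: str,
    pops: tuple[str, ...],
    values: np.ndarray,
    block_size: int,
) -> FStatResult:
    means, counts = _block_means(values, block_size)
    if means.shape[0] < 2:
        raise ValueError("fewer than 2 usable blocks")
    theta, se = _jackknife_scalar(means[:, 0], counts)
    z = theta / se if se > 0 else 0.0
    return FStatResult(
        stat_type=stat_type,
        populations=pops,
        value=theta,
        se=se,
        z=float(z),
        n_blocks=means.shape[0],
        n_snps=int(counts.sum()),
    )


def f2(matrix: GenotypeMatrix, A: str, B: str, block_size_snps: int = 500) -> FStatResult:
    """Mean squared frequency difference between two populations."""
    freqs, _ = pop_allele_freqs(matrix, [A, B])
    return _fstat("f2", (A, B), (freqs[A] - freqs[B]) ** 2, block_size_snps)


def f3(
    matrix: GenotypeMatrix, X: str, A: str, B: str, block_size_snps: int = 500
) -> FStatResult:
    """f3(X; A, B): negative values signal X is admixed between A and B."""
    freqs, _ = pop_allele_freqs(matrix, [X, A, B])
    vals = (freqs[X] - freqs[A]) * (freqs[X] - freqs[B])
    return _fstat("f3", (X, A, B), vals, block_size_snps)


def f4(
    matrix: GenotypeMatrix, A: str, B: str, C: str, D: str,
    block_size_snps: int = 500,
) -> FStatResult:
    """f4(A, B; C, D) with delete-one block jackknife SE."""
    freqs, _ = pop_allele_freqs(matrix, [A, B, C, D])
    vals = (freqs[A] - freqs[B]) * (freqs[C] - freqs[D])
    return _fstat("f4", (A, B, C, D), vals, block_size_snps)


# ---------------------------------------------------------------------------
# qpAdm-style fitting
# ---------------------------------------------------------------------------

def _f4_design(
    freqs: dict[str, np.ndarray],
    target: str,
    sources: tuple[str, ...],
    right_pops: tuple[str, ...],
    block_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block means of f4(T, S_s; R_j, R_0) for all (j, s).

    Returns ``(D, counts)`` where ``D`` has shape (n_blocks, m-1, k) and
    a single usable-site mask (any-NaN across all populations) is shared.
    """
    r0 = right_pops[0]
    cols = []
    for rj in right_pops[1:]:
        for s in sources:
            cols.append((freqs[target] - freqs[s]) * (freqs[rj] - freqs[r0]))
    flat = np.stack(cols, axis=1)  # (n_snps, (m-1)*k)
    means, counts = _block_means(flat, block_size)
    D = means.reshape(means.shape[0], len(right_pops) - 1, len(sources))
    return D, counts


def _solve_weights(M: np.ndarray) -> np.ndarray:
    """argmin a^T M a subject to sum(a)=1."""
    k = M.shape[0]
    ridge = 1e-12 * max(np.trace(M) / k, 1e-300)
    ones = np.ones(k)
    try:
        x = np.linalg.solve(M + ridge * np.eye(k), ones)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(M, ones, rcond=None)[0]
    return x / x.sum()


def _gls_alpha(
    D: np.ndarray, counts: np.ndarray, n_iter: int = 8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterated GLS for the mixture weights.

    Returns (alpha, Q, Bbar): the weights, the jackknife covariance of the
    residual vector at the final weights, and the overall design matrix.
    """
    n = counts.sum()
    Bbar = (D * counts[:, None, None]).sum(axis=0) / n  # (m-1, k)
    k = Bbar.shape[1]
    alpha = np.full(k, 1.0 / k)
    Q = None
    for _ in range(n_iter):
        r_blocks = D @ alpha  # (n_blocks, m-1)
        Q = _jackknife_cov(r_blocks, counts)
        Qinv = _safe_inv(Q)
        M = Bbar.T @ Qinv @ Bbar
        new = _solve_weights(M)
        if np.allclose(new, alpha, atol=1e-12):
            alpha = new
            break
        alpha = new
    return alpha, Q, Bbar


def _safe_inv(Q: np.ndarray) -> np.ndarray:
    q = Q.shape[0]
    scale = max(np.trace(Q) / q, 1e-300)
    try:
        cond = np.linalg.cond(Q)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("singular jackknife covariance; ridge-regularized", stacklevel=3)
        Q = Q + 1e-9 * scale * np.eye(q)
    return np.linalg.inv(Q)


def qpadm_fit(
    matrix: GenotypeMatrix,
    target: str,
    sources: list[str] | tuple[str, ...],
    right_pops: list[str] | tuple[str, ...],
    block_size_snps: int = 500,
) -> AdmixtureFit:
    """Estimate ancestry proportions of ``target`` from ``sources``.

    Weights solve the f4-system GLS under the sum-to-one constraint; the
    residual chi-square gives the model-fit p-value; feasibility flags
    whether all weights lie in [0, 1].
    """
    sources = tuple(sources)
    right_pops = tuple(right_pops)
    if not 2 <= len(sources) <= 5:
        raise ValueError("need between 2 and 5 source populations")
    if len(right_pops) < len(sources) + 1:
        raise ValueError(
            f"need at least {len(sources) + 1} right populations for "
            f"{len(sources)} sources"
        )
    freqs, _ = pop_allele_freqs(
        matrix, [target, *sources, *right_pops]
    )
    D, counts = _f4_design(freqs, target, sources, right_pops, block_size_snps)
    if D.shape[0] < 2:
        raise ValueError("fewer than 2 usable blocks")
    n = counts.sum()
    Bbar = (D * counts[:, None, None]).sum(axis=0) / n
    # two sources whose f4 profiles against the right panel coincide make
    # the system unidentifiable; col_a - col_b equals f4(S_b, S_a; R_j, R_0)
    norms = np.linalg.norm(Bbar, axis=0)
    scale = max(float(norms.max()), 1e-300)
    for a, b in itertools.combinations(range(len(sources)), 2):
        if np.linalg.norm(Bbar[:, a] - Bbar[:, b]) < 1e-9 * scale:
            raise ValueError(
                f"sources {sources[a]!r} and {sources[b]!r} are "
                "indistinguishable in f4 space (near-collinear)"
            )
    alpha, Q, Bbar = _gls_alpha(D, counts)
    resid = Bbar @ alpha
    stat = float(resid @ _safe_inv(Q) @ resid)
    dof = (len(right_pops) - 1) - (len(sources) - 1)
    p = float(sstats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    # jackknife SEs for the weights (covariance held fixed for speed)
    Qinv = _safe_inv(Q)
    B_tot = (D * counts[:, None, None]).sum(axis=0)
    loo_alphas = []
    for b in range(D.shape[0]):
        Bb = (B_tot - counts[b] * D[b]) / (n - counts[b])
        M = Bb.T @ Qinv @ Bb
        loo_alphas.append(_solve_weights(M))
    loo = np.asarray(loo_alphas)
    nb = loo.shape[0]
    se = np.sqrt((nb - 1) / nb * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    eps = 1e-9
    feasible = bool(np.all(alpha >= -eps) and np.all(alpha <= 1 + eps))
    return AdmixtureFit(
        target=target,
        sources=sources,
        weights=alpha,
        weight_se=se,
        p_value=p,
        feasible=feasible,
        dof=dof,
        n_blocks=D.shape[0],
    )


def model_scan(
    matrix: GenotypeMatrix,
    target: str,
    candidate_sources: list[str],
    right_pops: list[str],
    p_threshold: float = 0.05,
    min_k: int = 2,
    max_k: int = 5,
    block_size_snps: int = 500,
) -> ModelScanResult:
    """Evaluate every source subset of size ``min_k..max_k``.

    A model is accepted when it is feasible and its fit p-value exceeds the
    threshold; the selected model has the fewest sources, ties broken by
    higher p-value, then lexicographic source order.  When no model is
    accepted the result carries the full diagnostic ranking with an empty
    selection.
    """
    if len(candidate_sources) < min_k:
        raise ValueError("fewer candidate sources than min_k")
    evaluated: list[AdmixtureFit] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    for k in range(min_k, min(max_k, len(candidate_sources)) + 1):
        for combo in itertools.combinations(candidate_sources, k):
            try:
                evaluated.append(
                    qpadm_fit(matrix, target, combo, right_pops, block_size_snps)
                )
            except (ValueError, KeyError) as exc:
                failures.append((combo, str(exc)))
    accepted = [f for f in evaluated if f.feasible and f.p_value > p_threshold]
    selected = None
    if accepted:
        order = {tuple(c): i for i, c in enumerate(
            itertools.chain.from_iterable(
                itertools.combinations(candidate_sources, k)
                for k in range(min_k, min(max_k, len(candidate_sources)) + 1)
            )
        )}
        selected = min(
            accepted, key=lambda f: (len(f.sources), -f.p_value, order[f.sources])
        )
    return ModelScanResult(
        target=target,
        evaluated=evaluated,
        failures=failures,
        p_threshold=p_threshold,
        accepted=accepted,
        selected=selected,
    )


# ---------------------------------------------------------------------------
# qpWave-style rank test
# ---------------------------------------------------------------------------

def qpwave_rank_test(
    matrix: GenotypeMatrix,
    left_pops: list[str],
    right_pops: list[str],
    rank: int,
    block_size_snps: int = 500,
) -> float:
    """p-value for "the left/right f4 matrix has the given rank".

    Rank ``r`` corresponds to ``r + 1`` independent ancestry streams among
    the left populations relative to the right panel.  The statistic is the
    GLS distance between the observed f4 matrix and its best rank-``r``
    approximation under the block-jackknife covariance, referred to
    chi-square with ``(|left|-1-r)(|right|-1-r)`` degrees of freedom.
    """
    left = tuple(left_pops)
    right = tuple(right_pops)
    if len(left) < rank + 1 or len(right) < rank + 1:
        raise ValueError("need at least rank+1 left and right populations")
    nl, nr = len(left) - 1, len(right) - 1
    dof = (nl - rank) * (nr - rank)
    if dof <= 0:
        return 1.0
    freqs, _ = pop_allele_freqs(matrix, list(left) + list(right))
    cols = []
    for li in left[1:]:
        for rj in right[1:]:
            cols.append((freqs[li] - freqs[left[0]]) * (freqs[rj] - freqs[right[0]]))
    flat = np.stack(cols, axis=1)
    means, counts = _block_means(flat, block_size_snps)
    if means.shape[0] < 2:
        raise ValueError("fewer than 2 usable blocks")
    n = counts.sum()
    Fbar = (means * counts[:, None]).sum(axis=0) / n  # vec of (nl, nr)
    Q = _jackknife_cov(means, counts)
    Qinv = _safe_inv(Q)
    if rank == 0:
        stat = float(Fbar @ Qinv @ Fbar)
        return float(sstats.chi2.sf(stat, dof))
    # alternating GLS for the best rank-k approximation M = A @ Bt
    Fmat = Fbar.reshape(nl, nr)
    U, s, Vt = np.linalg.svd(Fmat, full_matrices=False)
    A = U[:, :rank] * s[:rank]
    Bt = Vt[:rank]
    stat_prev = np.inf
    stat = np.inf
    for _ in range(200):
        # row-major vec(A @ Bt) is linear in vec(A): block-diagonal design
        XA = np.zeros((nl * nr, nl * rank))
        for i in range(nl):
            XA[i * nr : (i + 1) * nr, i * rank : (i + 1) * rank] = Bt.T
        GA = XA.T @ Qinv @ XA
        gA = XA.T @ Qinv @ Fbar
        A = np.linalg.lstsq(GA, gA, rcond=None)[0].reshape(nl, rank)
        XB = np.zeros((nl * nr, nr * rank))
        for i in range(nl):
            for j in range(nr):
                XB[i * nr + j, j * rank : (j + 1) * rank] = A[i]
        GB = XB.T @ Qinv @ XB
        gB = XB.T @ Qinv @ Fbar
        Bt = np.linalg.lstsq(GB, gB, rcond=None)[0].reshape(nr, rank).T
        resid = Fbar - (A @ Bt).reshape(-1)
        stat = float(resid @ Qinv @ resid)
        if abs(stat_prev - stat) < 1e-10 * max(stat, 1.0):
            break
        stat_prev = stat
    return float(sstats.chi2.sf(max(stat, 0.0), dof))


# ---------------------------------------------------------------------------
# block bootstrap
# ---------------------------------------------------------------------------

def block_bootstrap_ci(
    matrix: GenotypeMatrix,
    target: str,
    sources: list[str] | tuple[str, ...],
    right_pops: list[str] | tuple[str, ...],
    n_reps: int = 1000,
    block_size_snps: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> AdmixtureFit:
    """Percentile block-bootstrap confidence intervals for the weights.

    SNP blocks are resampled with replacement ``n_reps`` times and the
    weights refit per replicate (the GLS covariance is held at the
    full-data estimate).  Reproducible given ``seed``; returns the original
    fit with ``bootstrap_ci`` populated.
    """
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} is small for percentile CIs", stacklevel=2)
    sources = tuple(sources)
    right_pops = tuple(right_pops)
    fit = qpadm_fit(matrix, target, sources, right_pops, block_size_snps)
    freqs, _ = pop_allele_freqs(matrix, [target, *sources, *right_pops])
    D, counts = _f4_design(freqs, target, sources, right_pops, block_size_snps)
    nb = D.shape[0]
    if nb < 10:
        raise ValueError(f"only {nb} usable blocks; need at least 10 to bootstrap")
    r_blocks = D @ fit.weights
    Q = _jackknife_cov(r_blocks, counts)
    Qinv = _safe_inv(Q)
    rng = child_rng(seed, "bootstrap", target, *sources)
    idx = rng.integers(0, nb, size=(n_reps, nb))
    Dsel = D[idx]  # (reps, nb, m-1, k)
    csel = counts[idx]  # (reps, nb)
    Bbar = np.einsum("rb,rbmk->rmk", csel, Dsel) / csel.sum(axis=1)[:, None, None]
    M = np.einsum("rmk,mn,rnl->rkl", Bbar, Qinv, Bbar)
    k = len(sources)
    ones = np.ones(k)
    ridge = 1e-12 * np.einsum("rkk->r", M) / k
    M = M + ridge[:, None, None] * np.eye(k)[None]
    x = np.linalg.solve(M, np.broadcast_to(ones[:, None], (n_reps, k, 1)).copy())[..., 0]
    alphas = x / x.sum(axis=1, keepdims=True)
    lo = (1.0 - level) / 2.0
    ci = {
        s: (
            float(np.quantile(alphas[:, i], lo)),
            float(np.quantile(alphas[:, i], 1.0 - lo)),
        )
        for i, s in enumerate(sources)
    }
    fit.bootstrap_ci = ci
    return fit
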