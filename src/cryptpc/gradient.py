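"""Distances, gradients, clustering and ordination in a PC subspace.

Once screening has picked the informative components (a marginal triple by
default), samples live in that low-dimensional Euclidean space.  This
module computes pairwise distances there, the distance from every sample
to its nearest member of each named reference set (the "gradient" view:
admixed samples sit at intermediate distances between their sources), Ward
hierarchical clustering, and classical (Torgerson) metric MDS.

Reference samples exclude themselves from their own set's nearest-neighbor
search; otherwise every reference would trivially sit at distance zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import cdist, squareform

from .pca import PCResult

__all__ = [
    "DistanceGradientTable",
    "pc_distance",
    "pairwise_pc_distances",
    "nearest_reference_distances",
    "ward_clustering",
    "linkage_to_newick",
    "classical_mds",
]


@dataclass
class DistanceGradientTable:
    """Per-sample nearest-reference distances in a PC subspace."""

    table: pd.DataFrame  # sample_id, population, then per-set distance + neighbor
    pc_subset: tuple[int, ...]
    reference_sets: dict[str, tuple[str, ...]]

    def population_means(self) -> pd.DataFrame:
        dist_cols = [c for c in self.table.columns if c.startswith("dist_")]
        return self.table.groupby("population", sort=True)[dist_cols].mean().reset_index()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _subset_coords(pc_result: PCResult, pc_subset: tuple[int, ...]) -> np.ndarray:
    idx = np.asarray(pc_subset, dtype=int) - 1
    if idx.size == 0:
        raise ValueError("pc_subset must be non-empty")
    if idx.min() < 0 or idx.max() >= pc_result.k:
        raise ValueError(f"pc_subset {pc_subset} outside 1..{pc_result.k}")
    return pc_result.scores[:, idx]


def pc_distance(
    scores_i: np.ndarray, scores_j: np.ndarray, pc_subset: tuple[int, ...]
) -> float:
    """Euclidean distance between two score vectors over a 1-based PC subset."""
    idx = np.asarray(pc_subset, dtype=int) - 1
    si, sj = np.asarray(scores_i, float), np.asarray(scores_j, float)
    if idx.max() >= si.size or idx.max() >= sj.size:
        raise ValueError("score vectors do not cover the requested components")
    return float(np.sqrt(((si[idx] - sj[idx]) ** 2).sum()))


def pairwise_pc_distances(pc_result: PCResult, pc_subset: tuple[int, ...]) -> pd.DataFrame:
    """Square symmetric distance matrix over all samples, as a DataFrame."""
    coords = _subset_coords(pc_result, pc_subset)
    d = cdist(coords, coords)
    return pd.DataFrame(d, index=pc_result.sample_ids, columns=pc_result.sample_ids)


def nearest_reference_distances(
    pc_result: PCResult,
    reference_sets: dict[str, tuple[str, ...] | list[str]],
    pc_subset: tuple[int, ...],
) -> DistanceGradientTable:
    """Distance from every sample to its nearest member of each reference set.

    Reference sets are named collections of population labels.  A sample
    belonging to a reference set is matched against the other members only.
    """
    coords = _subset_coords(pc_result, pc_subset)
    pops = np.asarray(pc_result.populations)
    out = pd.DataFrame(
        {"sample_id": pc_result.sample_ids, "population": pc_result.populations}
    )
    for name, labels in reference_sets.items():
        members = np.nonzero(np.isin(pops, list(labels)))[0]
        if members.size == 0:
            raise ValueError(f"reference set {name!r} resolves to no samples")
        d = cdist(coords, coords[members])
        for col, row in enumerate(members):  # self-exclusion
            d[row, col] = np.inf
        order = np.argmin(d, axis=1)
        best = d[np.arange(len(pops)), order]
        ids = np.asarray(pc_result.sample_ids)
        nn_ids = ids[members][order].astype(object)
        # a lone reference sample has no non-self neighbor in its own set
        lone = np.isinf(best)
        nn_ids[lone] = None
        out[f"dist_{name}"] = np.where(lone, np.nan, best)
        out[f"nearest_{name}"] = nn_ids
    return DistanceGradientTable(
        table=out,
        pc_subset=tuple(pc_subset),
        reference_sets={k: tuple(v) for k, v in reference_sets.items()},
    )


def ward_clustering(distance_matrix: np.ndarray) -> np.ndarray:
    """Ward (ward.D2) hierarchical clustering of a square distance matrix.

    Returns a SciPy linkage matrix; merge heights are non-decreasing.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    # condensed form; linkage applies the Lance–Williams ward.D2 update
    return linkage(squareform(d, checks=False), method="ward")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for r, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + r] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + r] = h
    return nodes[n + len(Z) - 1] + ";"


def classical_mds(distance_matrix: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS embedding.

    Double-centers the squared distances and embeds on the top eigenvectors.
    For Euclidean-realizable input the embedded pairwise distances reproduce
    the input to numerical precision.  If fewer than ``dims`` positive
    eigenvalues exist, the embedding is truncated with a warning.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, min(dims, 1)))
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]))
    n_pos = int(pos.sum())
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding truncated to {use} dims",
            stacklevel=2,
        )
    return evecs[:, :use] * np.sqrt(evals[:use])[None, :]
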