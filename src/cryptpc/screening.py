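"""Systematic marginal-PC screening.

Populations that share their dominant ancestry are often inseparable on
the leading principal components: the informative variation sits on a
low-variance "marginal" component.  This module screens every component
for population-extreme values, scores how well chosen groups separate in a
given PC subset, and searches all subsets of a fixed size (three-way by
default) for the best-discriminating subspace.

The discrimination score is a multi-group variance-ratio: between-group
scatter over within-group scatter, traced over the subset's dimensions on
per-component standardized scores and scaled by the usual F degrees of
freedom.  Traces make the score invariant to rotations inside the subset;
standardizing each component first keeps high-variance components from
drowning out marginal ones.  A label-permutation null is provided for
calibration, since the score's absolute scale has no universal meaning.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import PCResult

__all__ = [
    "DiscriminationSpec",
    "PCScreeningReport",
    "population_pc_stats",
    "detect_extremes",
    "discrimination_score",
    "screen_all_pcs",
    "search_pc_combinations",
    "permutation_null_scores",
]

_VAR_FLOOR = 1e-12  # guards zero within-group variance


@dataclass(frozen=True)
class DiscriminationSpec:
    """Named, disjoint groups of population labels to separate."""

    groups: dict[str, tuple[str, ...]]
    min_group_n: int = 3

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        seen: set[str] = set()
        for name, pops in self.groups.items():
            overlap = seen & set(pops)
            if overlap:
                raise ValueError(f"group {name!r} overlaps others on {sorted(overlap)}")
            seen |= set(pops)

    def group_rows(self, populations: list[str]) -> dict[str, np.ndarray]:
        """Resolve groups to sample row indices, enforcing min_group_n."""
        out = {}
        for name, pops in self.groups.items():
            rows = np.asarray(
                [i for i, p in enumerate(populations) if p in pops], dtype=int
            )
            if rows.size < self.min_group_n:
                raise ValueError(
                    f"group {name!r} resolves to {rows.size} samples "
                    f"(< min_group_n={self.min_group_n})"
                )
            out[name] = rows
        return out


@dataclass
class PCScreeningReport:
    """Output of the single-PC and subset-search screening stages."""

    stats: pd.DataFrame  # population, pc, mean, sd, n
    extremes: pd.DataFrame  # population, pc, z
    small_populations: list[str]  # excluded from flagging (n < min_group_n)
    single_pc_scores: pd.DataFrame  # pc, score
    ranked_triples: pd.DataFrame | None = None  # pcs, score (non-increasing)
    selected_triple: tuple[int, ...] | None = None
    z_threshold: float = 2.0

    def to_json(self, path=None) -> str:
        payload = {
            "z_threshold": self.z_threshold,
            "stats": self.stats.to_dict(orient="records"),
            "extremes": self.extremes.to_dict(orient="records"),
            "small_populations": self.small_populations,
            "single_pc_scores": self.single_pc_scores.to_dict(orient="records"),
            "ranked_triples": (
                None
                if self.ranked_triples is None
                else self.ranked_triples.assign(
                    pcs=self.ranked_triples.pcs.map(list)
                ).to_dict(orient="records")
            ),
            "selected_triple": (
                None if self.selected_triple is None else list(self.selected_triple)
            ),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def population_pc_stats(pc_result: PCResult) -> pd.DataFrame:
    """Per-(population, PC) mean, SD and n.

    SD is the sample standard deviation (ddof=1); populations of one sample
    report SD as NaN.
    """
    df = pc_result.to_frame()
    pcs = [c for c in df.columns if c.startswith("PC")]
    long = df.melt(
        id_vars=["population"], value_vars=pcs, var_name="pc", value_name="score"
    )
    long["pc"] = long.pc.str.removeprefix("PC").astype(int)
    stats = (
        long.groupby(["population", "pc"], sort=True)["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return stats


def detect_extremes(
    pc_result: PCResult,
    z_threshold: float = 2.0,
    min_group_n: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Flag populations whose PC mean is extreme against the global spread.

    Population ``P`` is flagged on component ``k`` iff
    ``|mean_P - global_mean| > z_threshold * global_SD``, with the global
    mean/SD taken over all sample scores on that component.  Populations
    with fewer than ``min_group_n`` samples are excluded from flagging and
    returned separately.
    """
    scores = pc_result.scores
    gmean = scores.mean(axis=0)
    gsd = scores.std(axis=0, ddof=1)
    if np.any(gsd <= 0):
        k = int(np.argmax(gsd <= 0)) + 1
        raise ValueError(f"PC{k} is degenerate (zero global SD)")
    stats = population_pc_stats(pc_result)
    small = sorted(
        stats.loc[stats.n < min_group_n, "population"].unique().tolist()
    )
    eligible = stats[stats.n >= min_group_n].copy()
    eligible["z"] = (
        eligible["mean"].to_numpy() - gmean[eligible.pc.to_numpy() - 1]
    ) / gsd[eligible.pc.to_numpy() - 1]
    flagged = (
        eligible[np.abs(eligible.z) > z_threshold][["population", "pc", "z"]]
        .sort_values(["pc", "population"])
        .reset_index(drop=True)
    )
    return flagged, small


def _per_pc_scatter(
    scores: np.ndarray, groups: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-component between/within sums of squares over the group samples.

    Scores are standardized per component (over the grouped samples) before
    the scatter decomposition, so each component enters on a common scale.
    """
    rows = np.concatenate(list(groups.values()))
    sub = scores[rows]
    sd = sub.std(axis=0, ddof=1)
    sub = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    grand = sub.mean(axis=0)
    between = np.zeros(scores.shape[1])
    within = np.zeros(scores.shape[1])
    offset = 0
    for rows_g in groups.values():
        g = sub[offset : offset + rows_g.size]
        offset += rows_g.size
        gm = g.mean(axis=0)
        between += rows_g.size * (gm - grand) ** 2
        within += ((g - gm[None, :]) ** 2).sum(axis=0)
    return between, within, len(groups), rows.size


def discrimination_score(
    pc_result: PCResult,
    spec: DiscriminationSpec,
    pc_subset: tuple[int, ...],
) -> float:
    """Multi-group F-ratio of the groups inside a PC subset (1-based PCs)."""
    if len(pc_subset) == 0:
        raise ValueError("pc_subset must be non-empty")
    groups = spec.group_rows(pc_result.populations)
    between, within, g, n = _per_pc_scatter(pc_result.scores, groups)
    idx = np.asarray(pc_subset, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= pc_result.k:
        raise ValueError(f"pc_subset {pc_subset} outside 1..{pc_result.k}")
    b = between[idx].sum() / (g - 1)
    w = within[idx].sum() / max(n - g, 1)
    return float(b / max(w, _VAR_FLOOR))


def screen_all_pcs(
    pc_result: PCResult,
    spec: DiscriminationSpec,
    z_threshold: float = 2.0,
) -> PCScreeningReport:
    """Single-PC screening stage: stats, extreme flags and per-PC scores."""
    stats = population_pc_stats(pc_result)
    extremes, small = detect_extremes(
        pc_result, z_threshold=z_threshold, min_group_n=spec.min_group_n
    )
    groups = spec.group_rows(pc_result.populations)
    between, within, g, n = _per_pc_scatter(pc_result.scores, groups)
    scores = (between / (g - 1)) / np.maximum(within / max(n - g, 1), _VAR_FLOOR)
    single = pd.DataFrame(
        {"pc": np.arange(1, pc_result.k + 1), "score": scores}
    )
    return PCScreeningReport(
        stats=stats,
        extremes=extremes,
        small_populations=small,
        single_pc_scores=single,
        z_threshold=z_threshold,
    )


def search_pc_combinations(
    pc_result: PCResult,
    spec: DiscriminationSpec,
    arity: int = 3,
) -> PCScreeningReport:
    """Exhaustive search over all C(K, arity) PC subsets.

    Returns the single-PC report augmented with the full non-increasing
    ranking of subsets and the argmax (ties broken by lexicographically
    smallest index tuple).
    """
    k = pc_result.k
    if arity > k:
        raise ValueError(f"arity={arity} exceeds K={k}")
    report = screen_all_pcs(pc_result, spec)
    groups = spec.group_rows(pc_result.populations)
    between, within, g, n = _per_pc_scatter(pc_result.scores, groups)
    combos = list(itertools.combinations(range(1, k + 1), arity))
    bsum = np.array([between[np.asarray(c) - 1].sum() for c in combos])
    wsum = np.array([within[np.asarray(c) - 1].sum() for c in combos])
    scores = (bsum / (g - 1)) / np.maximum(wsum / max(n - g, 1), _VAR_FLOOR)
    order = sorted(range(len(combos)), key=lambda i: (-scores[i], combos[i]))
    ranked = pd.DataFrame(
        {
            "pcs": [combos[i] for i in order],
            "score": [float(scores[i]) for i in order],
        }
    )
    report.ranked_triples = ranked
    report.selected_triple = tuple(ranked.pcs.iloc[0])
    return report


def permutation_null_scores(
    pc_result: PCResult,
    spec: DiscriminationSpec,
    pc_subset: tuple[int, ...],
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the score under random group-label permutation."""
    rng = np.random.default_rng(seed)
    groups = spec.group_rows(pc_result.populations)
    rows = np.concatenate(list(groups.values()))
    sizes = [g.size for g in groups.values()]
    idx = np.asarray(pc_subset, dtype=int) - 1
    out = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(rows)
        shuffled = {}
        off = 0
        for name, size in zip(groups, sizes):
            shuffled[name] = perm[off : off + size]
            off += size
        between, within, g, n = _per_pc_scatter(pc_result.scores, shuffled)
        b = between[idx].sum() / (g - 1)
        w = within[idx].sum() / max(n - g, 1)
        out[r] = b / max(w, _VAR_FLOOR)
    return out
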