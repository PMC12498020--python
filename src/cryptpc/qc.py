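"""Two-level genotype quality control.

SNP-level filters (minor allele frequency, Hardy–Weinberg equilibrium,
missingness, LD pruning) run first, then sample-level filters (coverage,
missingness, sex consistency, kinship).  Kinship runs last, on the
LD-pruned QC-passing sites, because IBD moment estimates assume roughly
independent markers.  Every removal is accounted for in a :class:`QCReport`.

The Hardy–Weinberg test is the conditional exact test (probability-ordering
two-sided convention): given the observed allele counts, the p-value sums
the probabilities of all heterozygote configurations no more probable than
the observed one.  It is computed on the pooled dataset; with strong
population structure this is conservative as a filter (Wahlund effect
depresses heterozygosity globally), which is the intended use here.

Relatedness uses the PLINK-style method-of-moments IBD estimator: observed
identity-by-state counts per pair are compared with their expectations
under IBD states 0/1/2 given pooled allele frequencies, yielding
``PI_HAT = P(IBD=2) + P(IBD=1)/2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, subset

__all__ = [
    "QCThresholds",
    "QCReport",
    "compute_maf",
    "hwe_exact_p",
    "ld_prune",
    "estimate_pi_hat",
    "apply_qc_pipeline",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common ancient-DNA practice."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    snp_missing_max: float = 0.80
    ld_r2_max: float = 0.25
    ld_window: int = 200
    ld_step: int = 50
    sample_min_snps: int = 50_000
    sample_missing_max: float = 0.80
    pi_hat_max: float = 0.25

    def __post_init__(self):
        for name in ("maf_min", "hwe_p_min", "snp_missing_max", "ld_r2_max",
                     "sample_missing_max", "pi_hat_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("need ld_window >= ld_step >= 1")
        if self.sample_min_snps < 0:
            raise ValueError("sample_min_snps must be >= 0")


@dataclass
class QCReport:
    """Per-stage accounting of the filtering cascade."""

    stages: list[dict] = field(default_factory=list)
    final_n_samples: int = 0
    final_n_snps: int = 0
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, axis: str, n_in: int, n_removed: int, threshold):
        self.stages.append(
            {
                "stage": name,
                "axis": axis,
                "n_in": int(n_in),
                "n_removed": int(n_removed),
                "threshold": threshold,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "stages": self.stages,
            "final_n_samples": self.final_n_samples,
            "final_n_snps": self.final_n_snps,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def compute_maf(matrix: GenotypeMatrix, snp_index: int) -> float:
    """Minor allele frequency at one site among non-missing calls.

    An all-missing site returns NaN, which every threshold comparison
    treats as a failing value.
    """
    col = matrix.calls[:, snp_index]
    obs = col[col != MISSING]
    if obs.size == 0:
        return float("nan")
    p = float(obs.sum()) / (2.0 * obs.size)
    return min(p, 1.0 - p)


def _maf_all(calls: np.ndarray) -> np.ndarray:
    obs = calls != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy–Weinberg p-value for one site's genotype counts.

    Conditions on the observed allele counts and sums P(h) over every
    heterozygote count h whose conditional probability does not exceed the
    observed configuration's (two-sided, probability ordering).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_Aa  # copies of the a allele
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:  # monomorphic: single configuration
        return 1.0
    # valid heterozygote counts share parity with the rare-allele count
    rare = min(n_a, n_A)
    hs = np.arange(rare % 2, rare + 1, 2)
    n_hom_rare = (rare - hs) // 2
    n_hom_common = n - hs - n_hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(hs + 1)
        - gammaln(n_hom_common + 1)
        + hs * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_A + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hs == n_Aa)[0][0]]
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())


def _hwe_all(calls: np.ndarray) -> np.ndarray:
    """Exact HWE p per SNP (pooled counts); all-missing sites get NaN."""
    out = np.empty(calls.shape[1])
    n_AA = (calls == 0).sum(axis=0)
    n_Aa = (calls == 1).sum(axis=0)
    n_aa = (calls == 2).sum(axis=0)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(calls.shape[1]):
        key = (int(n_AA[j]), int(n_Aa[j]), int(n_aa[j]))
        if sum(key) == 0:
            out[j] = np.nan
            continue
        if key not in cache:
            cache[key] = hwe_exact_p(*key)
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(calls: np.ndarray, min_obs: int) -> np.ndarray:
    """r^2 between SNP columns using pairwise-complete observations.

    Entries with fewer than ``min_obs`` complete pairs, or with zero
    variance on either side, are NaN.
    """
    M = (calls != MISSING).astype(float)
    V = np.where(calls == MISSING, 0.0, calls).astype(float)
    n = M.T @ M
    Sxy = V.T @ V
    Sx = V.T @ M  # (i,j): sum of x_i over sites observed in both
    Qx = (V * V).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / n
        varx = Qx - Sx**2 / n
        r2 = cov**2 / (varx * varx.T)
    r2[n < min_obs] = np.nan
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 200,
    step: int = 50,
    r2_max: float = 0.25,
    min_pair_obs: int = 20,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained snp_ids.

    Within each window (advanced by ``step`` SNPs, per chromosome), pairs of
    retained SNPs with genotype-dosage r^2 above ``r2_max`` lose their
    later-positioned member.  SNPs must already be sorted by
    (chromosome, physical position).  Pairs with fewer than ``min_pair_obs``
    complete observations are left alone (ancient-DNA missingness makes such
    r^2 estimates meaningless).
    """
    chroms = [s.chromosome for s in matrix.snps]
    pos = [s.physical_pos for s in matrix.snps]
    for j in range(1, matrix.n_snps):
        if chroms[j] == chroms[j - 1] and pos[j] < pos[j - 1]:
            raise ValueError(
                "SNPs are not sorted by (chromosome, physical_pos); "
                "sort the matrix before LD pruning"
            )
    keep = np.ones(matrix.n_snps, dtype=bool)
    # contiguous runs per chromosome (file order defines chromosome order)
    bounds: list[tuple[int, int]] = []
    start = 0
    for j in range(1, matrix.n_snps + 1):
        if j == matrix.n_snps or chroms[j] != chroms[start]:
            bounds.append((start, j))
            start = j
    for lo, hi in bounds:
        for w0 in range(lo, hi, step):
            idx = np.arange(w0, min(w0 + window, hi))
            idx = idx[keep[idx]]
            if idx.size < 2:
                continue
            r2 = _pairwise_r2(matrix.calls[:, idx], min_pair_obs)
            local_keep = np.ones(idx.size, dtype=bool)
            for a in range(idx.size):
                if not local_keep[a]:
                    continue
                for b in range(a + 1, idx.size):
                    if local_keep[b] and r2[a, b] > r2_max:
                        local_keep[b] = False
            keep[idx[~local_keep]] = False
    return [matrix.snps[j].snp_id for j in np.nonzero(keep)[0]]


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def estimate_pi_hat(
    matrix: GenotypeMatrix,
    pruned_snp_ids: list[str] | None = None,
    min_pair_snps: int = 100,
) -> pd.DataFrame:
    """Pairwise PLINK-style PI_HAT table.

    Returns a DataFrame with one row per unordered sample pair:
    ``sample_i, sample_j, n_snps, pi_hat``.  Pairs with fewer than
    ``min_pair_snps`` jointly observed sites are unevaluable (``pi_hat`` NaN).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    m = matrix if pruned_snp_ids is None else subset(matrix, snp_ids=pruned_snp_ids)
    calls = m.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    usable = (n_obs > 0) & (p > 0) & (p < 1)
    p = np.where(usable, p, np.nan)
    q = 1.0 - p
    # per-SNP P(IBS=i | IBD=z) under random mating at pooled frequencies
    e = {
        "00": 2 * p**2 * q**2,
        "01": 4 * p**3 * q + 4 * p * q**3,
        "02": p**4 + q**4 + 4 * p**2 * q**2,
        "11": 2 * p * q,  # P(IBS1|IBD1)
        "12": p**2 + q**2,  # P(IBS2|IBD1)
    }
    e = {k: np.where(usable, v, 0.0) for k, v in e.items()}
    Mu = (obs & usable).astype(float)
    # expected IBS counts per pair: sum of e over jointly observed usable sites
    E = {k: (Mu * v) @ Mu.T for k, v in e.items()}
    z0m = ((calls == 0) & usable).astype(float)
    z1m = ((calls == 1) & usable).astype(float)
    z2m = ((calls == 2) & usable).astype(float)
    I2 = z0m @ z0m.T + z1m @ z1m.T + z2m @ z2m.T
    I0 = z0m @ z2m.T + z2m @ z0m.T
    n_joint = Mu @ Mu.T
    I1 = n_joint - I2 - I0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z0 = I0 / E["00"]
        Z1 = (I1 - Z0 * E["01"]) / E["11"]
        # P(IBS2|IBD2) = 1, so the IBD2 denominator is the joint site count
        Z2 = (I2 - Z0 * E["02"] - Z1 * E["12"]) / n_joint
    Z0 = np.clip(np.nan_to_num(Z0, nan=1.0), 0.0, 1.0)
    Z1 = np.clip(np.nan_to_num(Z1, nan=0.0), 0.0, 1.0)
    Z2 = np.clip(np.nan_to_num(Z2, nan=0.0), 0.0, 1.0)
    total = Z0 + Z1 + Z2
    with np.errstate(invalid="ignore", divide="ignore"):
        Z1n = np.where(total > 0, Z1 / total, 0.0)
        Z2n = np.where(total > 0, Z2 / total, 0.0)
    pi_hat = np.clip(Z2n + 0.5 * Z1n, 0.0, 1.0)
    rows = []
    ids = m.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            nij = int(n_joint[i, j])
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "n_snps": nij,
                    "pi_hat": float(pi_hat[i, j]) if nij >= min_pair_snps else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_snps", "pi_hat"])


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def apply_qc_pipeline(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    declared_sex: dict[str, str] | None = None,
    strict_sex: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the full SNP-then-sample filtering cascade.

    Stage order: MAF -> HWE -> SNP missingness -> LD pruning -> sample
    coverage -> sample missingness -> sex check -> kinship.  For each
    related pair above ``pi_hat_max`` the member with fewer covered SNPs is
    removed (ties: the lexicographically later sample_id).  ``declared_sex``
    maps sample_id to an externally determined sex; mismatches against the
    matrix's own records warn, or remove the sample when ``strict_sex``.
    """
    report = QCReport()
    m = matrix

    def _require_nonempty(stage: str):
        if m.n_snps == 0 or m.n_samples == 0:
            raise ValueError(f"matrix empty after QC stage {stage!r}")

    # --- SNP-level ------------------------------------------------------
    maf = _maf_all(m.calls)
    keep = ~(np.isnan(maf) | (maf < thresholds.maf_min))
    report.add_stage("maf", "snp", m.n_snps, int((~keep).sum()), thresholds.maf_min)
    m = subset(m, snp_ids=[m.snps[j].snp_id for j in np.nonzero(keep)[0]])
    _require_nonempty("maf")

    hwe = _hwe_all(m.calls)
    keep = ~(np.isnan(hwe) | (hwe <= thresholds.hwe_p_min))
    report.add_stage("hwe", "snp", m.n_snps, int((~keep).sum()), thresholds.hwe_p_min)
    m = subset(m, snp_ids=[m.snps[j].snp_id for j in np.nonzero(keep)[0]])
    _require_nonempty("hwe")

    miss = (m.calls == MISSING).mean(axis=0)
    keep = miss <= thresholds.snp_missing_max
    report.add_stage(
        "snp_missingness", "snp", m.n_snps, int((~keep).sum()), thresholds.snp_missing_max
    )
    m = subset(m, snp_ids=[m.snps[j].snp_id for j in np.nonzero(keep)[0]])
    _require_nonempty("snp_missingness")

    retained = ld_prune(
        m, window=thresholds.ld_window, step=thresholds.ld_step, r2_max=thresholds.ld_r2_max
    )
    report.add_stage(
        "ld_prune", "snp", m.n_snps, m.n_snps - len(retained),
        f"r2<={thresholds.ld_r2_max},w={thresholds.ld_window},s={thresholds.ld_step}",
    )
    m = subset(m, snp_ids=retained)
    _require_nonempty("ld_prune")

    # --- sample-level ---------------------------------------------------
    covered = (m.calls != MISSING).sum(axis=1)
    keep = covered >= thresholds.sample_min_snps
    report.add_stage(
        "sample_coverage", "sample", m.n_samples, int((~keep).sum()),
        thresholds.sample_min_snps,
    )
    m = subset(m, sample_ids=[m.samples[i].sample_id for i in np.nonzero(keep)[0]])
    _require_nonempty("sample_coverage")

    smiss = (m.calls == MISSING).mean(axis=1)
    keep = smiss <= thresholds.sample_missing_max
    report.add_stage(
        "sample_missingness", "sample", m.n_samples, int((~keep).sum()),
        thresholds.sample_missing_max,
    )
    m = subset(m, sample_ids=[m.samples[i].sample_id for i in np.nonzero(keep)[0]])
    _require_nonempty("sample_missingness")

    n_removed_sex = 0
    if declared_sex is not None:
        mismatched = [
            s.sample_id
            for s in m.samples
            if s.sample_id in declared_sex
            and "U" not in (s.sex, declared_sex[s.sample_id])
            and s.sex != declared_sex[s.sample_id]
        ]
        for sid in mismatched:
            msg = f"sex mismatch for sample {sid} (metadata vs declared)"
            report.warnings.append(msg)
            warnings.warn(msg, stacklevel=2)
        if strict_sex and mismatched:
            n_removed_sex = len(mismatched)
            keep_ids = [s.sample_id for s in m.samples if s.sample_id not in mismatched]
            m = subset(m, sample_ids=keep_ids)
    report.add_stage(
        "sex_check", "sample", m.n_samples + n_removed_sex, n_removed_sex,
        "strict" if strict_sex else "warn",
    )
    _require_nonempty("sex_check")

    # --- kinship (last, on the pruned QC-passing set) -------------------
    # relatives are sought within populations, against that population's own
    # allele frequencies: pooled frequencies on a structured panel inflate
    # PI_HAT for every within-group pair in a drifted population
    drop: set[str] = set()
    tables = []
    for pop, rows in m.population_index().items():
        if rows.size < 2:
            continue
        tables.append(estimate_pi_hat(subset(m, sample_ids=[m.sample_ids[i] for i in rows])))
    if tables:
        table = pd.concat(tables, ignore_index=True)
        flagged = table[table.pi_hat > thresholds.pi_hat_max].sort_values(
            ["pi_hat", "sample_i", "sample_j"], ascending=[False, True, True]
        )
        coverage = dict(
            zip(m.sample_ids, (m.calls != MISSING).sum(axis=1).tolist())
        )
        for row in flagged.itertuples():
            if row.sample_i in drop or row.sample_j in drop:
                continue
            ci, cj = coverage[row.sample_i], coverage[row.sample_j]
            if ci < cj:
                drop.add(row.sample_i)
            elif cj < ci:
                drop.add(row.sample_j)
            else:
                drop.add(max(row.sample_i, row.sample_j))
    report.add_stage("kinship", "sample", m.n_samples, len(drop), thresholds.pi_hat_max)
    if drop:
        m = subset(m, sample_ids=[s for s in m.sample_ids if s not in drop])
    _require_nonempty("kinship")

    # sample removals can leave sites monomorphic or empty; re-apply the MAF
    # floor so the output is directly usable by PCA
    maf = _maf_all(m.calls)
    keep = ~(np.isnan(maf) | (maf < thresholds.maf_min))
    report.add_stage(
        "final_snp_cleanup", "snp", m.n_snps, int((~keep).sum()), thresholds.maf_min
    )
    if (~keep).any():
        m = subset(m, snp_ids=[m.snps[j].snp_id for j in np.nonzero(keep)[0]])
    _require_nonempty("final_snp_cleanup")

    report.final_n_samples = m.n_samples
    report.final_n_snps = m.n_snps
    return m, report
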