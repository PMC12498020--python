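"""QC filters: MAF, exact HWE, LD pruning, kinship, and cascade accounting."""

import math
from fractions import Fraction

import numpy as np
import pytest

from cryptpc.genotype_io import MISSING, GenotypeMatrix, SampleRecord, SNPRecord
from cryptpc.qc import (
    QCThresholds,
    apply_qc_pipeline,
    compute_maf,
    estimate_pi_hat,
    hwe_exact_p,
    ld_prune,
)
from conftest import random_matrix


def _matrix_from_calls(calls, populations=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    pops = populations or ["Pop"] * n
    return GenotypeMatrix(
        samples=[SampleRecord(f"S{i:02d}", pops[i]) for i in range(n)],
        snps=[
            SNPRecord(f"rs{j}", "1", j * 1e-4, 100 * (j + 1), "A", "C")
            for j in range(m)
        ],
        calls=calls,
    )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "calls,expected",
    [([0, 0, 1], 1 / 6), ([2, 2, 2], 0.0), ([1, 1, MISSING], 0.5)],
)
def test_compute_maf_examples(calls, expected):
    m = _matrix_from_calls(np.asarray(calls)[:, None])
    assert compute_maf(m, 0) == pytest.approx(expected)


def test_compute_maf_all_missing_is_nan():
    m = _matrix_from_calls(np.asarray([MISSING, MISSING])[:, None])
    assert math.isnan(compute_maf(m, 0))


# ---------------------------------------------------------------------------
# HWE exact test against exhaustive enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n - n_a
    if n_a == 0 or n_A == 0:
        return 1.0
    rare = min(n_a, n_A)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        probs[h] = (
            Fraction(math.factorial(n), math.factorial(hr) * math.factorial(h) * math.factorial(hc))
            * Fraction(2) ** h
            * Fraction(math.factorial(n_a) * math.factorial(n_A), math.factorial(2 * n))
        )
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def test_hwe_matches_enumeration_for_all_small_tables():
    """Agreement with the exact-rational oracle for every table with n <= 20."""
    for n in range(1, 21):
        for n_AA in range(n + 1):
            for n_Aa in range(n - n_AA + 1):
                n_aa = n - n_AA - n_Aa
                expected = hwe_enumeration_oracle(n_AA, n_Aa, n_aa)
                assert hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
                    expected, abs=1e-12
                ), (n_AA, n_Aa, n_aa)


def test_hwe_examples():
    assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0, abs=1e-9)
    assert hwe_exact_p(50, 0, 50) < 1e-6
    assert hwe_exact_p(1, 0, 0) == 1.0
    with pytest.raises(ValueError, match="non-negative"):
        hwe_exact_p(-1, 2, 3)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_removes_one_of_duplicated_pair(rng):
    base = rng.integers(0, 3, size=50).astype(np.int8)
    other = rng.integers(0, 3, size=(50, 3)).astype(np.int8)
    calls = np.column_stack([base, other[:, 0], base, other[:, 1], other[:, 2]])
    m = _matrix_from_calls(calls)
    kept = ld_prune(m, window=5, step=2, r2_max=0.25)
    assert "rs0" in kept and "rs2" not in kept  # later duplicate removed
    assert len(kept) >= 3


def test_ld_prune_keeps_independent_snps(rng):
    """SNPs drawn independently stay; verified by direct r^2 computation."""
    calls = rng.binomial(2, 0.5, size=(200, 40)).astype(np.int8)
    m = _matrix_from_calls(calls)
    kept = ld_prune(m, window=40, step=10, r2_max=0.25)
    removed = set(m.snp_ids) - set(kept)
    # anything removed must genuinely exceed the threshold against a peer
    corr = np.corrcoef(calls.T) ** 2
    np.fill_diagonal(corr, 0.0)
    for sid in removed:
        j = m.snp_ids.index(sid)
        assert corr[j].max() > 0.25


def test_ld_prune_window_one_removes_nothing(small_matrix):
    kept = ld_prune(small_matrix, window=1, step=1, r2_max=0.0)
    assert kept == small_matrix.snp_ids


def test_ld_prune_requires_sorted_snps(rng):
    m = random_matrix(rng, n_samples=4, n_snps=4)
    snps = list(m.snps)
    snps[0], snps[1] = snps[1], snps[0]
    unsorted = GenotypeMatrix(samples=m.samples, snps=snps, calls=m.calls)
    with pytest.raises(ValueError, match="sort"):
        ld_prune(unsorted)


# ---------------------------------------------------------------------------
# PI_HAT
# ---------------------------------------------------------------------------

def test_pi_hat_duplicate_pair_near_one(rng):
    calls = rng.binomial(2, rng.uniform(0.1, 0.9, 500), size=(6, 500)).astype(np.int8)
    calls[1] = calls[0]  # exact duplicate
    m = _matrix_from_calls(calls)
    tab = estimate_pi_hat(m)
    pair = tab[(tab.sample_i == "S00") & (tab.sample_j == "S01")]
    assert pair.pi_hat.iloc[0] > 0.9


def test_pi_hat_unrelated_near_zero(rng):
    p = rng.uniform(0.1, 0.9, 2000)
    calls = rng.binomial(2, p, size=(8, 2000)).astype(np.int8)
    m = _matrix_from_calls(calls)
    tab = estimate_pi_hat(m)
    assert tab.pi_hat.max() < 0.05


def test_pi_hat_parent_offspring_near_half(rng):
    p = rng.uniform(0.1, 0.9, 3000)
    parent = rng.binomial(2, p, size=3000).astype(np.int8)
    # child: one allele transmitted from the parent, one from the population
    transmitted = np.where(parent == 1, rng.integers(0, 2, 3000), parent // 2)
    child = (transmitted + rng.binomial(1, p)).astype(np.int8)
    others = rng.binomial(2, p, size=(4, 3000)).astype(np.int8)
    m = _matrix_from_calls(np.vstack([parent, child, others]))
    tab = estimate_pi_hat(m)
    pair = tab[(tab.sample_i == "S00") & (tab.sample_j == "S01")]
    assert pair.pi_hat.iloc[0] == pytest.approx(0.5, abs=0.1)


def test_pi_hat_sparse_pair_unevaluable(rng):
    calls = rng.binomial(2, 0.5, size=(3, 120)).astype(np.int8)
    calls[1, 50:] = MISSING
    calls[0, :80] = MISSING  # overlap with S01 = 0 usable sites < 100
    m = _matrix_from_calls(calls)
    tab = estimate_pi_hat(m)
    pair = tab[(tab.sample_i == "S00") & (tab.sample_j == "S01")]
    assert math.isnan(pair.pi_hat.iloc[0])


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

VACUOUS = QCThresholds(
    maf_min=0.0, hwe_p_min=0.0, snp_missing_max=1.0, ld_r2_max=1.0,
    sample_min_snps=0, sample_missing_max=1.0, pi_hat_max=1.0,
)


def _accounting_fixture(rng):
    """60 samples x 10 SNPs: exactly 3 MAF failures then 1 HWE failure."""
    n = 60
    cols = []
    # 6 well-behaved common sites near HWE
    for p in (0.3, 0.4, 0.5, 0.35, 0.45, 0.25):
        cols.append(rng.binomial(2, p, n))
    # 3 MAF violations: minor allele count 1 of 120 (freq < 0.01)
    for _ in range(3):
        col = np.zeros(n, dtype=int)
        col[0] = 1
        cols.append(col)
    # 1 HWE violation that passes MAF: all heterozygotes
    cols.append(np.ones(n, dtype=int))
    calls = np.column_stack(cols).astype(np.int8)
    return _matrix_from_calls(calls)


def test_qc_accounting_known_violations(rng):
    m = _accounting_fixture(rng)
    # oracle recount: verify the construction before trusting the report
    from cryptpc.qc import compute_maf, hwe_exact_p

    maf_fail = sum(compute_maf(m, j) < 0.01 for j in range(m.n_snps))
    assert maf_fail == 3
    filtered, report = apply_qc_pipeline(
        m, QCThresholds(sample_min_snps=0, ld_r2_max=1.0)
    )
    stages = {s["stage"]: s for s in report.stages}
    assert stages["maf"]["n_removed"] == 3
    assert stages["hwe"]["n_removed"] == 1
    assert filtered.n_snps == 6


def test_qc_stage_accounting_chains(rng):
    m = random_matrix(rng, n_samples=30, n_snps=40, missing_rate=0.1)
    filtered, report = apply_qc_pipeline(m, QCThresholds(sample_min_snps=1))
    for axis in ("snp", "sample"):
        chain = [s for s in report.stages if s["axis"] == axis]
        for prev, nxt in zip(chain, chain[1:]):
            assert prev["n_in"] - prev["n_removed"] == nxt["n_in"]
        total_removed = sum(s["n_removed"] for s in chain)
        start = chain[0]["n_in"]
        final = report.final_n_snps if axis == "snp" else report.final_n_samples
        assert start - total_removed == final


def test_qc_vacuous_thresholds_identity(rng):
    m = random_matrix(rng, n_samples=10, n_snps=20, missing_rate=0.1)
    filtered, report = apply_qc_pipeline(m, VACUOUS)
    assert filtered == m
    assert all(s["n_removed"] == 0 for s in report.stages)


def test_qc_idempotent(rng):
    m = random_matrix(rng, n_samples=30, n_snps=40, missing_rate=0.1)
    thr = QCThresholds(sample_min_snps=1)
    once, _ = apply_qc_pipeline(m, thr)
    twice, rep2 = apply_qc_pipeline(once, thr)
    assert twice == once


def test_qc_duplicate_sample_removed(rng):
    p = rng.uniform(0.2, 0.8, 400)
    calls = rng.binomial(2, p, size=(8, 400)).astype(np.int8)
    calls[1] = calls[0]
    m = _matrix_from_calls(calls)
    filtered, report = apply_qc_pipeline(
        m, QCThresholds(sample_min_snps=0, ld_r2_max=1.0)
    )
    stages = {s["stage"]: s for s in report.stages}
    assert stages["kinship"]["n_removed"] == 1
    # tie-break removes the lexicographically later id when coverage ties
    assert "S00" in filtered.sample_ids and "S01" not in filtered.sample_ids


def test_qc_empty_after_stage_raises(rng):
    calls = np.tile([0, 0, 2, 2], (4, 1)).T.astype(np.int8)  # MAF 0.5 everywhere
    m = _matrix_from_calls(calls)
    with pytest.raises(ValueError, match="maf"):
        apply_qc_pipeline(m, QCThresholds(maf_min=0.9, sample_min_snps=0))


def test_qc_sex_mismatch_warns(rng):
    m = random_matrix(rng, n_samples=10, n_snps=30, missing_rate=0.0)
    declared = {m.sample_ids[0]: "F" if m.samples[0].sex == "M" else "M"}
    with pytest.warns(UserWarning, match="sex mismatch"):
        _, report = apply_qc_pipeline(m, VACUOUS, declared_sex=declared)
    assert report.warnings
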