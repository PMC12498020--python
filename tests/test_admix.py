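"""f-statistics, qpAdm-style fitting, qpWave rank test, model scan, bootstrap."""

import numpy as np
import pytest

from cryptpc.admix import (
    block_bootstrap_ci,
    f2,
    f3,
    f4,
    model_scan,
    pop_allele_freqs,
    qpadm_fit,
    qpwave_rank_test,
)
from cryptpc.genotype_io import MISSING, GenotypeMatrix, SampleRecord, SNPRecord
from cryptpc.simulate import (
    AdmixtureEvent,
    PopulationSpec,
    ScenarioSpec,
    make_decoy_scan_scenario,
    make_two_source_scenario,
    simulate_scenario,
)

RIGHTS = tuple(f"Outgroup{i}" for i in range(1, 5))


def _matrix_from_calls(calls, populations):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return GenotypeMatrix(
        samples=[SampleRecord(f"S{i:02d}", populations[i]) for i in range(n)],
        snps=[
            SNPRecord(f"rs{j}", "1", j * 1e-4, 100 * (j + 1), "A", "C")
            for j in range(m)
        ],
        calls=calls,
    )


@pytest.fixture(scope="module")
def four_pop_matrix():
    rng = np.random.default_rng(77)
    n_per, n_snps = 10, 3000
    pops = []
    blocks = []
    for name in ("A", "B", "C", "D"):
        p = rng.uniform(0.1, 0.9, n_snps)
        calls = rng.binomial(2, p, size=(n_per, n_snps)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        blocks.append(calls)
        pops += [name] * n_per
    return _matrix_from_calls(np.vstack(blocks), pops)


# ---------------------------------------------------------------------------
# population frequencies
# ---------------------------------------------------------------------------

def test_pop_freqs_basic_and_masking():
    m = _matrix_from_calls([[0], [2], [MISSING], [MISSING]], ["P", "P", "Q", "Q"])
    freqs, counts = pop_allele_freqs(m, ["P", "Q"])
    assert freqs["P"][0] == pytest.approx(0.5)
    assert np.isnan(freqs["Q"][0])
    assert counts["P"][0] == 2 and counts["Q"][0] == 0


def test_pop_freqs_match_manual_recount(four_pop_matrix):
    m = four_pop_matrix
    freqs, counts = pop_allele_freqs(m, ["B"])
    rows = [i for i, p in enumerate(m.populations) if p == "B"]
    for j in (0, 100, 2999):
        col = m.calls[rows, j]
        obs = col[col != MISSING]
        assert freqs["B"][j] == pytest.approx(obs.sum() / (2 * obs.size))
        assert counts["B"][j] == obs.size


def test_pop_freqs_unknown_population(four_pop_matrix):
    with pytest.raises(KeyError, match="Nope"):
        pop_allele_freqs(four_pop_matrix, ["Nope"])


# ---------------------------------------------------------------------------
# f-statistics
# ---------------------------------------------------------------------------

def test_f4_identical_first_pair_is_exactly_zero(four_pop_matrix):
    r = f4(four_pop_matrix, "A", "A", "C", "D", block_size_snps=300)
    assert r.value == 0.0


def test_f4_antisymmetry_exact(four_pop_matrix):
    m = four_pop_matrix
    r = f4(m, "A", "B", "C", "D", block_size_snps=300)
    assert f4(m, "B", "A", "C", "D", block_size_snps=300).value == -r.value
    assert f4(m, "A", "B", "D", "C", block_size_snps=300).value == -r.value


def test_f4_matches_bruteforce_oracle(four_pop_matrix):
    """Two-pass naive recomputation from raw calls agrees to 1e-12."""
    m = four_pop_matrix
    r = f4(m, "A", "B", "C", "D", block_size_snps=300)
    # oracle: plain python loops over populations and sites
    by_pop = {}
    for name in "ABCD":
        rows = [i for i, p in enumerate(m.populations) if p == name]
        by_pop[name] = m.calls[rows]
    vals = []
    for j in range(m.n_snps):
        ps = {}
        ok = True
        for name in "ABCD":
            col = by_pop[name][:, j]
            obs = col[col != MISSING]
            if obs.size == 0:
                ok = False
                break
            ps[name] = obs.sum() / (2 * obs.size)
        if ok:
            vals.append((ps["A"] - ps["B"]) * (ps["C"] - ps["D"]))
    assert r.value == pytest.approx(np.mean(vals), abs=1e-12)
    assert r.n_snps == len(vals)


def test_f4_null_z_small_under_symmetric_tree():
    """Independently drifted quartet: |Z| < 3 in at least 9/10 seeds."""
    ok = 0
    for seed in range(10):
        spec = ScenarioSpec(
            n_snps=10_000,
            populations=tuple(
                PopulationSpec(lab, 0.05, 15) for lab in ("A", "B", "C", "D")
            ),
            missing_rate=0.2,
            seed=seed,
        )
        m = simulate_scenario(spec).matrix
        ok += abs(f4(m, "A", "B", "C", "D").z) < 3
    assert ok >= 9


def test_fstat_block_requirements():
    m = _matrix_from_calls(
        np.random.default_rng(0).binomial(2, 0.5, (8, 300)).astype(np.int8),
        ["A"] * 2 + ["B"] * 2 + ["C"] * 2 + ["D"] * 2,
    )
    with pytest.raises(ValueError, match="2 usable blocks"):
        f4(m, "A", "B", "C", "D", block_size_snps=500)


def test_f2_f3_basic(four_pop_matrix):
    assert f2(four_pop_matrix, "A", "A", block_size_snps=300).value == 0.0
    r = f3(four_pop_matrix, "A", "B", "C", block_size_snps=300)
    assert np.isfinite(r.value) and r.se > 0


# ---------------------------------------------------------------------------
# qpAdm
# ---------------------------------------------------------------------------

def test_qpadm_degenerate_target_copies_source():
    """Target identical in frequency to source 1 gets weight ~ (1, 0)."""
    spec = make_two_source_scenario(1.0, seed=3, n_snps=20_000)
    m = simulate_scenario(spec).matrix
    fit = qpadm_fit(m, "Target", ("Baltic", "Balkan"), RIGHTS)
    assert fit.weights[0] == pytest.approx(1.0, abs=0.05)


def test_qpadm_two_source_recovery():
    """alpha = 0.57 mixture recovered within +/- 0.05 at 20k SNPs, n=30."""
    spec = make_two_source_scenario(0.57, seed=11)
    m = simulate_scenario(spec).matrix
    fit = qpadm_fit(m, "Target", ("Baltic", "Balkan"), RIGHTS)
    assert fit.weights[0] == pytest.approx(0.57, abs=0.05)
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert fit.feasible


def test_qpadm_three_source_recovery():
    """Three-way mixture (0.592, 0.209, 0.199) recovered within +/- 0.07."""
    labels = ("EWSlavic", "Byzantine", "Steppe")
    pops = tuple(PopulationSpec(lab, 0.08, 30) for lab in labels)
    from cryptpc.simulate import _outgroup_panel

    deep, og = _outgroup_panel(labels, n_deep=2)
    events = (
        AdmixtureEvent("AvarSlav", labels, (0.592, 0.209, 0.199), 30),
    ) + og
    spec = ScenarioSpec(
        n_snps=20_000, populations=pops + deep, admixture_events=events, seed=5
    )
    m = simulate_scenario(spec).matrix
    rights = tuple(f"Outgroup{i}" for i in range(1, 6))
    fit = qpadm_fit(m, "AvarSlav", labels, rights)
    for w, truth in zip(fit.weights, (0.592, 0.209, 0.199)):
        assert w == pytest.approx(truth, abs=0.07)


def test_qpadm_invariant_to_right_reordering():
    spec = make_two_source_scenario(0.4, seed=2)
    m = simulate_scenario(spec).matrix
    a = qpadm_fit(m, "Target", ("Baltic", "Balkan"), RIGHTS)
    b = qpadm_fit(m, "Target", ("Baltic", "Balkan"), RIGHTS[::-1])
    assert np.allclose(a.weights, b.weights, atol=1e-6)


def test_qpadm_rejects_duplicate_sources():
    spec = make_two_source_scenario(0.5, seed=4, n_snps=4000)
    sim = simulate_scenario(spec)
    m = sim.matrix
    # a literal relabeled copy of Baltic is indistinguishable in f4 space
    copy_rows = [i for i, p in enumerate(m.populations) if p == "Baltic"]
    extra = GenotypeMatrix(
        samples=m.samples
        + [
            SampleRecord(f"CP{i:02d}", "BalticCopy")
            for i in range(len(copy_rows))
        ],
        snps=m.snps,
        calls=np.vstack([m.calls, m.calls[copy_rows]]),
    )
    with pytest.raises(ValueError, match="collinear|indistinguishable"):
        qpadm_fit(extra, "Target", ("Baltic", "BalticCopy"), RIGHTS)


def test_qpadm_needs_enough_rights():
    spec = make_two_source_scenario(0.5, seed=4, n_snps=2000)
    m = simulate_scenario(spec).matrix
    with pytest.raises(ValueError, match="right populations"):
        qpadm_fit(m, "Target", ("Baltic", "Balkan"), RIGHTS[:2])


# ---------------------------------------------------------------------------
# qpWave
# ---------------------------------------------------------------------------

def test_qpwave_copied_population_rank0_holds():
    from cryptpc.simulate import make_null_copy_scenario

    m = simulate_scenario(make_null_copy_scenario(seed=1)).matrix
    p = qpwave_rank_test(m, ["Src", "Copy"], list(RIGHTS), 0)
    assert p > 0.05


def test_qpwave_diverged_sources_need_rank1():
    m = simulate_scenario(make_two_source_scenario(0.5, seed=6)).matrix
    p0 = qpwave_rank_test(m, ["Baltic", "Balkan"], list(RIGHTS), 0)
    p1 = qpwave_rank_test(m, ["Baltic", "Balkan"], list(RIGHTS), 1)
    assert p0 < 0.01
    assert p1 > 0.05


# ---------------------------------------------------------------------------
# model scan
# ---------------------------------------------------------------------------

def test_model_scan_boundary_threshold():
    m = simulate_scenario(make_decoy_scan_scenario(seed=1, n_snps=6000)).matrix
    rights = [f"Outgroup{i}" for i in range(1, 7)]
    res = model_scan(
        m, "Target", ["Baltic", "Balkan", "DecoyA"], rights,
        p_threshold=1.0, min_k=2, max_k=2,
    )
    assert len(res.evaluated) + len(res.failures) == 3  # C(3,2)
    assert res.accepted == [] and res.selected is None
    assert len(res.summary()) == 3


def test_model_scan_selects_true_pair():
    m = simulate_scenario(make_decoy_scan_scenario(seed=8)).matrix
    rights = [f"Outgroup{i}" for i in range(1, 7)]
    res = model_scan(
        m, "Target", ["Baltic", "Balkan", "DecoyA", "DecoyB"], rights
    )
    assert res.selected is not None
    assert set(res.selected.sources) == {"Baltic", "Balkan"}


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_under_seed():
    m = simulate_scenario(make_two_source_scenario(0.57, seed=9, n_snps=10_000)).matrix
    a = block_bootstrap_ci(m, "Target", ("Baltic", "Balkan"), RIGHTS, n_reps=200, seed=5)
    b = block_bootstrap_ci(m, "Target", ("Baltic", "Balkan"), RIGHTS, n_reps=200, seed=5)
    assert a.bootstrap_ci == b.bootstrap_ci
    lo, hi = a.bootstrap_ci["Baltic"]
    assert lo < hi


def test_bootstrap_small_reps_warns():
    m = simulate_scenario(make_two_source_scenario(0.5, seed=9, n_snps=10_000)).matrix
    with pytest.warns(UserWarning, match="small"):
        block_bootstrap_ci(m, "Target", ("Baltic", "Balkan"), RIGHTS, n_reps=50, seed=1)


def test_bootstrap_zero_admixture_boundary():
    """alpha = (1, 0) truth: the null source's lower CI bound is near zero."""
    m = simulate_scenario(make_two_source_scenario(1.0, seed=13)).matrix
    fit = block_bootstrap_ci(m, "Target", ("Baltic", "Balkan"), RIGHTS, n_reps=500, seed=3)
    assert fit.bootstrap_ci["Balkan"][0] <= 0.05
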