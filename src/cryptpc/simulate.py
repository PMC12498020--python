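"""Balding–Nichols admixture simulator with plantable cryptic signatures.

The generator emulates the statistical structure of a multi-population
ancient-DNA panel:

* ancestral allele frequencies drawn per SNP (uniform on [0.05, 0.95] by
  default);
* each source population drifts from the ancestor under the Balding–Nichols
  model, ``p_pop ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, where ``F`` plays the role
  of an Fst-style drift parameter;
* admixed populations mix source *frequencies* (``p_target = sum_s a_s p_s``)
  and may drift a little further after admixture;
* diploid calls are Binomial(2, p) per individual, optionally collapsed to
  pseudo-haploid {0, 2}; missingness is uniform per call;
* an optional planted "cryptic" signature shifts frequencies by a small
  ``delta`` at a random subset of SNPs for the affected populations only —
  producing two groups that share their dominant ancestry yet are separable
  on a marginal principal component.

All randomness descends from a single integer seed through keyed substreams
(:mod:`cryptpc._rand`), so identical specs reproduce byte-identical matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rand import child_rng
from .genotype_io import MISSING, GenotypeMatrix, SampleRecord, SNPRecord

__all__ = [
    "PopulationSpec",
    "AdmixtureEvent",
    "SignatureSpec",
    "ScenarioSpec",
    "SimulationResult",
    "simulate_scenario",
    "plant_marginal_signature",
    "make_study_scenario",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class PopulationSpec:
    """A population drifted directly from the common ancestor."""

    label: str
    fst: float  # Balding–Nichols drift parameter, in (0, 1)
    n_samples: int
    role: str = "source"

    def __post_init__(self):
        if not 0 < self.fst < 1:
            raise ValueError(f"{self.label}: drift parameter must be in (0, 1)")
        if self.n_samples < 0:
            raise ValueError(f"{self.label}: negative sample count")


@dataclass(frozen=True)
class AdmixtureEvent:
    """An admixed population formed by mixing source allele frequencies."""

    target_label: str
    source_labels: tuple[str, ...]
    proportions: tuple[float, ...]
    n_samples: int
    post_admixture_fst: float = 0.0  # extra drift after admixture; 0 = none
    role: str = "target"

    def __post_init__(self):
        if len(self.source_labels) != len(self.proportions):
            raise ValueError(f"{self.target_label}: sources/proportions length mismatch")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"{self.target_label}: proportions sum to {sum(self.proportions)}, not 1"
            )
        if any(a < 0 for a in self.proportions):
            raise ValueError(f"{self.target_label}: negative proportion")
        if not 0 <= self.post_admixture_fst < 1:
            raise ValueError(f"{self.target_label}: post-admixture drift out of range")


@dataclass(frozen=True)
class SignatureSpec:
    """A planted low-variance differentiating component.

    Frequencies of the affected populations are shifted by ``delta`` at
    ``n_signature_snps`` randomly chosen sites; everything else is untouched,
    so the signature contributes little overall variance and is invisible on
    the leading principal components.
    """

    affected_labels: tuple[str, ...]
    n_signature_snps: int
    delta: float


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of a synthetic demographic scenario."""

    n_snps: int
    populations: tuple[PopulationSpec, ...]
    admixture_events: tuple[AdmixtureEvent, ...] = ()
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.3
    pseudo_haploid: bool = False
    signature: SignatureSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        labels = [p.label for p in self.populations] + [
            e.target_label for e in self.admixture_events
        ]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels in scenario")
        known = {p.label for p in self.populations}
        for e in self.admixture_events:
            unknown = set(e.source_labels) - known
            if unknown:
                raise ValueError(
                    f"{e.target_label}: unknown source populations {sorted(unknown)}"
                )


@dataclass
class SimulationResult:
    """Genotypes plus the ground truth the scenario was built from."""

    matrix: GenotypeMatrix
    truth: pd.DataFrame  # one row per (target, source) with true proportion
    frequencies: dict[str, np.ndarray]  # per-population true allele freqs
    signature_snps: np.ndarray  # indices of planted-signature SNPs (may be empty)


def _drift(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """One round of Balding–Nichols drift away from frequencies ``p``."""
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1.0 - p) * scale, 1e-9))


def _draw_calls(
    p: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    pseudo_haploid: bool,
) -> np.ndarray:
    if pseudo_haploid:
        # one sampled allele reported twice — the standard aDNA random-draw call
        return (2 * rng.binomial(1, p, size=(n_samples, p.size))).astype(np.int8)
    return rng.binomial(2, p, size=(n_samples, p.size)).astype(np.int8)


def simulate_scenario(spec: ScenarioSpec) -> SimulationResult:
    """Simulate genotypes and ground truth for a scenario.

    Deterministic given ``spec`` (including its seed): every random draw
    comes from a substream keyed by purpose and population label.
    """
    seed = spec.seed
    lo, hi = spec.ancestral_freq_range
    p_anc = child_rng(seed, "ancestral").uniform(lo, hi, size=spec.n_snps)

    freqs: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for pop in spec.populations:
        freqs[pop.label] = _drift(p_anc, pop.fst, child_rng(seed, "drift", pop.label))
        roles[pop.label] = pop.role
    truth_rows = []
    for ev in spec.admixture_events:
        p = np.zeros(spec.n_snps)
        for lab, a in zip(ev.source_labels, ev.proportions):
            p += a * freqs[lab]
            truth_rows.append(
                {"target": ev.target_label, "source": lab, "proportion": a}
            )
        freqs[ev.target_label] = _drift(
            p, ev.post_admixture_fst, child_rng(seed, "postdrift", ev.target_label)
        )
        roles[ev.target_label] = ev.role

    signature_snps = np.empty(0, dtype=int)
    if spec.signature is not None and spec.signature.delta != 0.0:
        sig = spec.signature
        if sig.n_signature_snps > spec.n_snps:
            raise ValueError("n_signature_snps exceeds n_snps")
        for lab in sig.affected_labels:
            if lab not in freqs:
                raise ValueError(f"signature population {lab!r} not in scenario")
        rng = child_rng(seed, "signature")
        signature_snps = np.sort(
            rng.choice(spec.n_snps, size=sig.n_signature_snps, replace=False)
        )
        for lab in sig.affected_labels:
            shifted = freqs[lab].copy()
            shifted[signature_snps] = np.clip(
                shifted[signature_snps] + sig.delta, 0.0, 1.0
            )
            freqs[lab] = shifted

    counts = {p.label: p.n_samples for p in spec.populations}
    counts.update({e.target_label: e.n_samples for e in spec.admixture_events})

    samples: list[SampleRecord] = []
    blocks: list[np.ndarray] = []
    for label in counts:
        n = counts[label]
        if n == 0:
            continue
        calls = _draw_calls(
            freqs[label], n, child_rng(seed, "calls", label), spec.pseudo_haploid
        )
        if spec.missing_rate > 0:
            mask = (
                child_rng(seed, "missing", label).random(calls.shape)
                < spec.missing_rate
            )
            calls[mask] = MISSING
        blocks.append(calls)
        samples.extend(
            SampleRecord(
                sample_id=f"{label}_{i:03d}", population=label, role=roles[label]
            )
            for i in range(n)
        )

    snps = [
        SNPRecord(
            snp_id=f"snp{j:06d}",
            chromosome="1",
            genetic_pos=j * 1e-6,
            physical_pos=j + 1,
            ref_allele="A",
            alt_allele="G",
        )
        for j in range(spec.n_snps)
    ]
    calls = (
        np.concatenate(blocks, axis=0)
        if blocks
        else np.empty((0, spec.n_snps), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples=samples, snps=snps, calls=calls)
    truth = pd.DataFrame(truth_rows, columns=["target", "source", "proportion"])
    return SimulationResult(
        matrix=matrix, truth=truth, frequencies=freqs, signature_snps=signature_snps
    )


def plant_marginal_signature(
    matrix: GenotypeMatrix,
    signature: SignatureSpec,
    seed: int,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Plant a cryptic frequency shift into an existing matrix.

    For each affected population, the observed alt-allele frequency at a
    random subset of ``n_signature_snps`` sites is shifted by ``delta``
    (clipped to [0, 1], with a warning if clipping occurs) and the
    population's non-missing calls at those sites are redrawn from the
    shifted frequency.  ``delta = 0`` returns the matrix unchanged.

    Returns the new matrix and the planted SNP indices.
    """
    if signature.n_signature_snps > matrix.n_snps:
        raise ValueError("n_signature_snps exceeds matrix SNP count")
    pop_index = matrix.population_index()
    for lab in signature.affected_labels:
        if lab not in pop_index:
            raise ValueError(f"population {lab!r} not present in matrix")
    if signature.delta == 0.0:
        return matrix, np.empty(0, dtype=int)
    rng = child_rng(seed, "plant")
    sites = np.sort(
        rng.choice(matrix.n_snps, size=signature.n_signature_snps, replace=False)
    )
    calls = matrix.calls.copy()
    for lab in signature.affected_labels:
        rows = pop_index[lab]
        sub = calls[np.ix_(rows, sites)].astype(float)
        obs = np.where(sub == MISSING, np.nan, sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
            p = np.nanmean(obs, axis=0) / 2.0
        p = np.where(np.isnan(p), 0.5, p)
        shifted = p + signature.delta
        if ((shifted < 0) | (shifted > 1)).any():
            warnings.warn(
                f"signature shift clipped to [0, 1] for population {lab}",
                stacklevel=2,
            )
        shifted = np.clip(shifted, 0.0, 1.0)
        new = rng.binomial(2, np.broadcast_to(shifted, sub.shape)).astype(np.int8)
        new[sub == MISSING] = MISSING
        calls[np.ix_(rows, sites)] = new
    out = GenotypeMatrix(samples=list(matrix.samples), snps=list(matrix.snps), calls=calls)
    return out, sites


# ---------------------------------------------------------------------------
# named study scenarios
# ---------------------------------------------------------------------------

def _outgroup_panel(
    sister_of: tuple[str, ...], n_deep: int = 2, n_samples: int = 15
) -> tuple[tuple[PopulationSpec, ...], tuple[AdmixtureEvent, ...]]:
    """A right-population panel differentially related to the sources.

    f4-statistics carry information about mixture weights only when the
    right populations share drift differentially with the sources, so the
    panel pairs one sister outgroup per listed source (a drifted daughter
    of that source's frequencies) with ``n_deep`` deeply drifted
    independent outgroups.
    """
    events = tuple(
        AdmixtureEvent(
            target_label=f"Outgroup{i + 1}",
            source_labels=(lab,),
            proportions=(1.0,),
            n_samples=n_samples,
            post_admixture_fst=0.12,
            role="outgroup",
        )
        for i, lab in enumerate(sister_of)
    )
    deep = tuple(
        PopulationSpec(
            label=f"Outgroup{len(sister_of) + j + 1}",
            fst=0.30 + 0.05 * j,
            n_samples=n_samples,
            role="outgroup",
        )
        for j in range(n_deep)
    )
    return deep, events


SCENARIO_NAMES = ("barbaricum5", "gradient", "three_wave")


def make_study_scenario(
    name: str, n_snps: int = 20_000, seed: int = 0
) -> ScenarioSpec:
    """Return a fully parameterized spec for one of the named study scenarios.

    ``barbaricum5``
        One target mixing five balanced ancestral components
        (proportions 0.218 / 0.211 / 0.205 / 0.194 / 0.172).
    ``gradient``
        Five targets along a Baltic-analogue admixture cline,
        alpha in {0, 0.25, 0.5, 0.75, 1}.
    ``three_wave``
        Three migration-wave targets with Baltic-analogue fractions
        0.55, 0.275 and 0.375 (midpoints of the waves' reported ranges).
    """
    if name == "barbaricum5":
        labels = ("Germanic", "Balkan_IA", "Proto_Slavic", "Byzantine", "Steppe")
        raw = np.array([21.5, 20.8, 20.2, 19.1, 16.9])
        props = tuple(np.round(raw / raw.sum(), 3))
        sources = tuple(
            PopulationSpec(label=lab, fst=0.08, n_samples=30) for lab in labels
        )
        # a five-source model needs six right populations: one sister
        # outgroup per source plus one deep outgroup
        deep, og_events = _outgroup_panel(labels, n_deep=1)
        events = (
            AdmixtureEvent(
                target_label="Barbaricum",
                source_labels=labels,
                proportions=props,
                n_samples=30,
            ),
        ) + og_events
        return ScenarioSpec(
            n_snps=n_snps,
            populations=sources + deep,
            admixture_events=events,
            seed=seed,
        )
    if name == "gradient":
        sources = (
            PopulationSpec(label="Baltic_BA", fst=0.08, n_samples=30, role="reference"),
            PopulationSpec(label="Balkan_IA", fst=0.08, n_samples=30, role="reference"),
        )
        deep, og_events = _outgroup_panel(("Baltic_BA", "Balkan_IA"))
        events = tuple(
            AdmixtureEvent(
                target_label=f"Cline_{int(100 * a):03d}",
                source_labels=("Baltic_BA", "Balkan_IA"),
                proportions=(a, 1.0 - a),
                n_samples=15,
            )
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
        ) + og_events
        return ScenarioSpec(
            n_snps=n_snps,
            populations=sources + deep,
            admixture_events=events,
            seed=seed,
        )
    if name == "three_wave":
        sources = (
            PopulationSpec(label="Baltic_BA", fst=0.08, n_samples=30, role="reference"),
            PopulationSpec(label="Balkan_IA", fst=0.08, n_samples=30, role="reference"),
        )
        deep, og_events = _outgroup_panel(("Baltic_BA", "Balkan_IA"))
        waves = (("Wave1_Early", 0.55), ("Wave2_Avar", 0.275), ("Wave3_Late", 0.375))
        events = tuple(
            AdmixtureEvent(
                target_label=lab,
                source_labels=("Baltic_BA", "Balkan_IA"),
                proportions=(a, 1.0 - a),
                n_samples=20,
            )
            for lab, a in waves
        ) + og_events
        return ScenarioSpec(
            n_snps=n_snps,
            populations=sources + deep,
            admixture_events=events,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; options: {', '.join(SCENARIO_NAMES)}")


def make_two_source_scenario(
    alpha: float,
    seed: int,
    n_snps: int = 20_000,
    n_samples: int = 30,
    source_labels: tuple[str, str] = ("Baltic", "Balkan"),
    target_label: str = "Target",
) -> ScenarioSpec:
    """One admixed target from two sources, with the standard right panel.

    The panel pairs a sister outgroup per source with two deep outgroups
    (``Outgroup1..Outgroup4``) — the configuration the admixture criteria
    are evaluated under.
    """
    pops = (
        PopulationSpec(source_labels[0], 0.08, n_samples),
        PopulationSpec(source_labels[1], 0.08, n_samples),
    )
    deep, og = _outgroup_panel(source_labels)
    events = (
        AdmixtureEvent(
            target_label, source_labels, (alpha, 1.0 - alpha), n_samples
        ),
    ) + og
    return ScenarioSpec(
        n_snps=n_snps, populations=pops + deep, admixture_events=events, seed=seed
    )


def make_decoy_scan_scenario(
    seed: int,
    alpha: float = 0.57,
    n_snps: int = 20_000,
    n_samples: int = 30,
) -> ScenarioSpec:
    """Two true sources plus two decoy populations, six right populations.

    The target mixes ``Baltic``/``Balkan``; ``DecoyA``/``DecoyB`` are
    independently drifted non-contributors.  Each candidate has a sister
    outgroup in the right panel so a model scan can tell them apart.
    """
    cands = ("Baltic", "Balkan", "DecoyA", "DecoyB")
    pops = (
        PopulationSpec("Baltic", 0.08, n_samples),
        PopulationSpec("Balkan", 0.08, n_samples),
        PopulationSpec("DecoyA", 0.08, n_samples),
        PopulationSpec("DecoyB", 0.12, n_samples),
    )
    deep, og = _outgroup_panel(cands, n_deep=2)
    events = (
        AdmixtureEvent("Target", ("Baltic", "Balkan"), (alpha, 1.0 - alpha), n_samples),
    ) + og
    return ScenarioSpec(
        n_snps=n_snps, populations=pops + deep, admixture_events=events, seed=seed
    )


def make_null_copy_scenario(
    seed: int, n_snps: int = 20_000, n_samples: int = 30
) -> ScenarioSpec:
    """A population and an undrifted copy of it (one ancestry stream).

    ``Copy`` shares ``Src``'s exact allele frequencies (independent
    genotype draws), so a rank-0 test of (Src, Copy) against the right
    panel holds under the null.
    """
    pops = (PopulationSpec("Src", 0.08, n_samples),)
    deep, og = _outgroup_panel(("Src",), n_deep=3)
    events = (
        AdmixtureEvent("Copy", ("Src",), (1.0,), n_samples, post_admixture_fst=0.0),
    ) + og
    return ScenarioSpec(
        n_snps=n_snps, populations=pops + deep, admixture_events=events, seed=seed
    )


def make_cryptic_scenario(
    n_snps: int = 20_000,
    n_per_group: int = 30,
    delta: float = 0.3,
    signature_fraction: float = 0.02,
    seed: int = 0,
) -> ScenarioSpec:
    """Two sibling groups sharing dominant ancestry, one carrying a signature.

    ``GroupA`` and ``GroupB`` both descend from the same drifted source
    (small independent post-split drift), so leading PCs cannot separate
    them; two well-drifted anchor populations supply the dominant variance
    axes.  A frequency shift of ``delta`` on ``signature_fraction`` of SNPs
    is planted into ``GroupB`` only, recoverable on a marginal PC.
    """
    shared = PopulationSpec(label="SharedAncestry", fst=0.06, n_samples=0)
    # several well-drifted anchors supply the dominant variance axes, so the
    # sibling-group split can only surface on a marginal component
    anchors = (
        PopulationSpec(label="AnchorWest", fst=0.12, n_samples=n_per_group),
        PopulationSpec(label="AnchorEast", fst=0.15, n_samples=n_per_group),
        PopulationSpec(label="AnchorNorth", fst=0.18, n_samples=n_per_group),
        PopulationSpec(label="AnchorSouth", fst=0.22, n_samples=n_per_group),
    )
    events = tuple(
        AdmixtureEvent(
            target_label=lab,
            source_labels=("SharedAncestry",),
            proportions=(1.0,),
            n_samples=n_per_group,
            post_admixture_fst=0.004,
        )
        for lab in ("GroupA", "GroupB")
    )
    return ScenarioSpec(
        n_snps=n_snps,
        populations=(shared,) + anchors,
        admixture_events=events,
        signature=SignatureSpec(
            affected_labels=("GroupB",),
            n_signature_snps=int(round(signature_fraction * n_snps)),
            delta=delta,
        ),
        seed=seed,
    )
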