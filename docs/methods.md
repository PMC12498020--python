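# Methods

## The problem

Two populations that share their dominant ancestry component are often
indistinguishable in the leading principal components of a genotype
matrix: PC1–PC2 capture the largest frequency differences in the panel,
and a subtle split between sibling groups contributes almost no variance.
The package's core method makes that split findable: screen *all*
components for group-discriminating signal, score candidate PC subsets
with a statistic that does not care how much variance a component
explains, and verify any finding with formal f4-based admixture modeling.

## Quality control

SNP-level filters run first, sample-level filters second, kinship last:

| stage | statistic | default threshold |
|---|---|---|
| maf | minor allele frequency over non-missing calls | ≥ 0.01 |
| hwe | conditional exact Hardy–Weinberg p (probability-ordering, two-sided) | > 10⁻⁶ |
| snp_missingness | fraction missing per site | ≤ 0.80 |
| ld_prune | pairwise dosage r² in sliding windows | r² ≤ 0.25, 200-SNP window, 50-SNP step |
| sample_coverage | non-missing sites per sample | ≥ 50,000 (scaled to panel size for synthetic data) |
| sample_missingness | fraction missing per sample | ≤ 0.80 |
| sex_check | metadata vs declared sex | warn (remove only in strict mode) |
| kinship | PI_HAT method-of-moments IBD | ≤ 0.25 |

Design points worth knowing:

* **HWE on the pooled panel.** Listing HWE as a global SNP filter on a
  structured dataset mixes populations; the Wahlund effect depresses
  heterozygosity, so the exact test mostly flags genotyping artifacts with
  extreme heterozygote excess. We keep the pooled convention deliberately
  and set the threshold very low (10⁻⁶).
* **Kinship within populations.** The PLINK-style PI_HAT estimator
  compares observed identity-by-state with expectations under the *panel*
  allele frequencies. For a population drifted F from the panel average,
  every within-population pair looks "related" (PI_HAT ≈ 2F/(1+F); F = 0.35
  already exceeds the 0.25 cutoff), and a naive pooled computation
  removes entire drifted populations. The pipeline therefore searches for
  relatives within populations, against each population's own
  frequencies. The standalone `estimate_pi_hat` keeps pooled frequencies
  (the PLINK convention) for cross-population use.
* **Removal rule for related pairs:** the member with fewer covered SNPs
  is dropped; coverage ties go against the lexicographically later
  sample id, so results are deterministic.
* **Final SNP cleanup.** Sample removals can leave sites monomorphic;
  a final MAF re-check guarantees the output meets the PCA precondition.
* The LD r² is computed on pairwise-complete observations, and pairs with
  fewer than 20 complete observations are skipped — with aDNA missingness
  such r² estimates are noise.
* The cascade is not provably idempotent in general (sample removals can
  change site statistics), but is idempotent in practice whenever the
  sample stages remove nobody or removals do not flip any site past a
  threshold; the test suite checks idempotence on representative panels.

## PCA

Sites are standardized by `(g − 2p̂) / sqrt(p̂(1−p̂))` with a shrunk
frequency estimate `p̂ = (1 + Σg) / (2 + 2n)` (posterior mean under a
uniform prior), after mean-imputing missing calls — the standard Patterson
scaling. Components come from the eigendecomposition of the sample-sample
covariance; score columns have unit norm, so absolute magnitudes depend on
sample count and are comparable only within one analysis. All samples are
co-fitted by default (matching a single-pass workflow); least-squares
projection of held-out samples onto the fitted loadings, using each
sample's observed sites only, is available separately and uses the
fit-time standardization statistics. Eigenvector signs are arbitrary, so
each component is oriented to give the anchor population (alphabetically
first by default) a non-negative mean score; without this, extreme-value
reports would not be reproducible.

## Marginal-PC screening

* **Per-PC population statistics**: mean, SD, n for every (population,
  component); singleton populations report SD as undefined and are never
  flagged (minimum group size 3 by default).
* **Extreme detection**: population P is flagged on component k when
  |mean_P − mean_global| > z·SD_global with z = 2 by default. The global
  baseline is over all sample scores, which is robust to uneven
  population sizes. Note the shifted samples themselves contribute to the
  global SD: a shift carried by a large fraction of the panel partially
  masks itself, which is the intended behavior of a *screening* statistic.
* **Discrimination score** for a group specification and PC subset: each
  component is standardized over the grouped samples, then the score is
  `[tr B/(g−1)] / [tr W/(n−g)]` with B and W the between/within-group
  scatter restricted to the subset — a multi-group F-ratio. Traces make it
  invariant to rotations inside the subset; standardization makes it scale
  invariant; a variance floor of 1e-12 handles point-mass groups. The
  score's absolute scale is not interpretable; a label-permutation null
  (`permutation_null_scores`) provides calibration.
* **Subset search**: all C(K, arity) subsets (1,140 for K = 20, arity = 3)
  are evaluated exhaustively; per-component scatter is precomputed so each
  subset costs O(arity). Ties break on the lexicographically smallest
  index tuple.

## Distances, clustering, ordination

Distances are plain Euclidean in the selected PC subspace (the screening
winner by default). Nearest-reference tables exclude a reference sample
from its own set's search — otherwise every reference sits at distance
zero. Ward clustering uses the ward.D2 (squared-distance Lance–Williams)
update via SciPy; dendrograms export as Newick with branch lengths.
Classical MDS is the Torgerson construction (double-centered squared
distances, top eigenvectors); if fewer positive eigenvalues exist than
requested dimensions the embedding truncates with a warning.

## Admixture modeling

All f-statistics are computed from population allele frequencies; a site
is used only when every participating population has at least one call.

* **f4 with block jackknife.** f4(A,B;C,D) is the mean over usable SNPs of
  (p_A−p_B)(p_C−p_D). SEs come from a delete-one jackknife over blocks of
  500 consecutive SNPs (the synthetic data carry no genetic map; blocks
  restore approximate independence under linkage). Blocks are weighted by
  their usable-SNP counts in the point estimate; the jackknife treats
  them as exchangeable, which is accurate for near-equal blocks.
* **Weight estimation.** With Σα = 1, the model residual for right
  population R_j is r_j(α) = Σ_s α_s · f4(T, S_s; R_j, R_0). Weights
  minimize rᵀQ⁻¹r where Q is the block-jackknife covariance of r; because
  Q depends on α, the GLS is iterated (a handful of fixed-point steps
  suffice). The minimized statistic is chi-square with
  (|right|−1) − (|sources|−1) degrees of freedom, giving the fit p-value.
  Weight SEs come from a leave-one-block-out refit with Q held fixed.
  Feasibility means every weight lies in [0, 1]; infeasible models are
  rejected in model selection rather than truncated.
* **Identifiability needs an informative right panel.** Under a star
  topology (every population drifting independently from one ancestor)
  all f4 expectations vanish and the weights are unidentifiable. The
  simulator's panels therefore pair one *sister* outgroup per source (a
  further-drifted daughter of that source's frequencies) with deep
  independent outgroups — the "differentially related" structure real
  right panels must have. Two sources whose f4 profiles against the panel
  coincide (e.g. duplicated populations) raise an explicit error.
* **Rank test.** The matrix F_ij = f4(L_i, L_0; R_j, R_0) has rank r when
  r + 1 ancestry streams relate the left to the right populations. The
  statistic is the GLS distance between F and its best rank-r
  approximation under the jackknife covariance (alternating generalized
  least squares over the low-rank factors), referred to chi-square with
  (|L|−1−r)(|R|−1−r) degrees of freedom. Singular covariances are
  ridge-regularized with a warning.
* **Model selection** scans every source subset of size 2–5, accepts
  feasible fits with p > 0.05, and selects the accepted model with the
  fewest sources (ties: higher p, then lexicographic order) — encoding
  "minimum number of streams first".
* **Block bootstrap.** SNP blocks are resampled with replacement
  (1,000 replicates by default) and the weights refit per replicate with
  the GLS covariance held at the full-data estimate (the covariance is a
  nuisance parameter here; holding it fixed makes the replicates cheap
  and the intervals stable). Percentile 95 % intervals are reported;
  everything is reproducible from one seed.

## The simulator

`simulate_scenario` draws ancestral frequencies per SNP (uniform on
[0.05, 0.95] by default), drifts each source population with the
Balding–Nichols Beta distribution parameterized by an Fst-style F, forms
admixed populations by mixing source *frequencies* with the stated
proportions (optionally followed by further drift), and draws diploid
calls Binomial(2, p) — or pseudo-haploid {0, 2} calls — with uniform
per-call missingness (0.3 by default, typical of ancient panels). A
planted signature shifts the affected populations' frequencies by δ at a
random SNP subset. All randomness flows from one integer seed through
substreams keyed by purpose and population label, so adding a step never
perturbs another step's draws and identical specs give byte-identical
output.

Default study conditions (chosen once, used by tests and the acceptance
script): 20,000 SNPs; 30 samples per analysis group; source drift
F = 0.08; sister-outgroup post-drift F = 0.12; deep outgroups F = 0.30
and 0.35; cryptic-signature δ = 0.3 on 2 % of SNPs; sibling-group
post-split drift F = 0.004 under four anchor populations, which puts the
planted split on a marginal component (typically PC5) rather than a
leading one.

What the simulator does *not* emulate: recombination and haplotype
structure (admixture is at the frequency level), reference bias, DNA
damage, contamination, or non-uniform missingness correlated with
coverage. Passing tests therefore demonstrate the statistical machinery
is correct and calibrated under the model's assumptions — not that any
particular empirical dataset will behave as cleanly.

Named scenarios: `barbaricum5` (one target mixing five balanced
components, proportions 0.218/0.211/0.205/0.194/0.172), `gradient` (five
targets along a two-source cline at α ∈ {0, 0.25, 0.5, 0.75, 1}), and
`three_wave` (three targets at Baltic-analogue fractions 0.55, 0.275,
0.375 — midpoints of the motivating ranges, documented as such).

## Numerical choices and degenerate inputs

* HWE uses log-gamma arithmetic with a (1 + 1e-12) slack in the
  probability-ordering comparison to absorb floating-point ties.
* PCA requires every site to have ≥ 2 calls and nonzero MAF and tells the
  caller to run QC otherwise; QC's final cleanup stage guarantees this.
* Degenerate components (zero global SD) are an error in extreme
  detection, not silently skipped.
* `model_scan` records subsets it cannot evaluate (too few right
  populations, collinear sources) as failures with reasons instead of
  aborting the scan.
* Chi-square tests with zero degrees of freedom (saturated rank tests)
  return p = 1.

## Known limitations

* Frequency-level f-statistics lack the small-sample bias corrections of
  genotype-based estimators; with ≥ 15 samples per population (the
  simulated regime) the bias is negligible, but very small empirical
  groups would need the corrected estimators.
* The jackknife/bootstrap block length is fixed in SNP count; when a
  genetic map is available, centimorgan-based blocking would be
  preferable for empirical data.
* The screening score assumes groups with roughly comparable covariance;
  strongly heteroscedastic groups would call for a Welch-style variant.
* Pipeline QC defaults scale the coverage floor to the synthetic panel
  size; empirical runs should restore the 50,000-site floor.
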