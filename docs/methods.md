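# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Covariate adjustment

Imputed expression is residualized gene-by-gene by OLS on an intercept
plus the demographic covariates (default: sex, age, `pc_1..pc_4`).
Two deliberate choices:

- **The phenotype is never a regressor.** Adjusting "for the phenotype"
  can be read two ways; regressing case/control status out before
  testing it would destroy the signal, so the residualization uses only
  nuisance covariates and the phenotype enters as the downstream
  contrast. This is stated on the API and asserted by a test (a pure
  case/control shift survives adjustment unchanged).
- **Expression-derived PCs are a fallback.** The PCs meant to absorb
  population structure ideally come from genotypes. When the sample
  table carries no `pc_` columns, the top PCs of the per-gene
  standardized expression matrix are used instead and the provenance is
  recorded in the run manifest. Four PCs is the default.

Constant or linearly dependent covariate columns are dropped with a
warning; samples with missing covariates are dropped listwise (logged).
Residuals are exactly orthogonal to every design column (checked to
1e-8·n) and adjustment is idempotent.

## Moderated t (empirical Bayes)

The two-group model per gene: effect = difference of class means of the
adjusted expression, residual variance s²_g on d_g degrees of freedom.
Variances are assumed drawn from a scaled inverse chi-square prior; the
marginal of s²_g is then a scaled F, and the hyperparameters (d₀, s₀²)
are estimated by matching the mean and variance of log s²_g corrected by
digamma/trigamma terms, with the trigamma inverse solved by Newton
iteration. The posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g) always lies between s²_g and s₀²;
t̃ = effect/(s̃·u) with u the unscaled SE, on d₀+d_g df (capped at the
pooled residual df). Limits behave correctly: d₀=0 reproduces the
classical t exactly; d₀→∞ pools fully to s₀². With fewer than 10 genes
the hyperparameter fit is unreliable and the code falls back to the
ordinary t with a warning. One test pins the whole chain to frozen
reference values computed independently with the standard
empirical-Bayes implementation in R on a fixed dataset (agreement to
~1e-8).

Two-sided p-values are used throughout. Direction information is
deliberately discarded at the next stage (see below).

## Dense module search

Node weights are z = Φ⁻¹(1−p). Clipping is done in z-space at
±Φ⁻¹(1−10⁻¹⁶) ≈ ±8.2221, which is exactly equivalent to clipping p into
[10⁻¹⁶, 1−10⁻¹⁶] but avoids the fact that 1−10⁻¹⁶ is not representable
in double precision. One-tailed weighting means a small p gives a large
weight regardless of effect direction; direction-split searches are out
of scope.

The module score is Z_m = Σz_i/√k. Growth from each seed: candidates are
weighted genes within shortest-path distance d (default 1) of the
module; the candidate maximizing the new score is accepted iff
Z_new > Z_old(1+r), r = 0.1 by default — the published dense-module
defaults. Ties break lexicographically, so runs are fully deterministic.
With d > 1 an accepted candidate brings the weighted genes on one
shortest path back to the module (lexicographically smallest path) and
is scored over that whole addition, so module members always induce a
connected subgraph. Genes present in the network but absent from the
differential table are removed from the graph before searching rather
than given an imputed minimum weight, which would fabricate evidence.

Normalization uses a weight-label permutation null: n_perm (default
1000) uniformly random gene sets of the same size k drawn from the
weighted genes, giving Z_N = (Z_m−μ_k)/σ_k and the add-one empirical
p = (1+#{null ≥ Z_m})/(n_perm+1), which can never be zero. When all
weights are equal the null is degenerate (σ_k = 0 up to rounding, which
is detected with a relative 1e-12 tolerance) and Z_N is defined as 0
with a warning. Selection keeps the top fraction (default 1%) of
modules by Z_N with p < 0.05 and deduplicates identical member sets.
A degree-preserving null is not implemented; the size-matched random-set
null mirrors the established normalization and is what the calibration
tests certify.

## Cross-population rotation

For each discovery population (lexicographic order of the other two:
first = evaluation, second = combination cohort):

- **Evaluation** re-scores each discovery module with the evaluation
  cohort's weights over the covered members only (size k′) and
  normalizes against a size-k′ null built from those weights. Modules
  with coverage below 50% are marked non-evaluable instead of being
  scored on one or two genes — per-tissue imputable gene sets genuinely
  differ, and a module scored on a sliver of itself is not a
  replication.
- **Combination** is an equal-weight Stouffer sum
  (Z_N,disc+Z_N,eval+Z_N,third)/√3, assessed against the per-draw
  Stouffer combination of the three cohorts' normalized null draws. A
  module is *shared* iff this combined empirical p < 0.05. The
  alternative intersection rule (require per-cohort significance) is
  available by filtering on the per-cohort `validated` flags. Stouffer
  was chosen because it is the natural Z-scale combination and degrades
  gracefully when one cohort is underpowered.

Because each population detects a shared module through its own effect
genes, triple-shared modules from different rotations typically overlap
only partially. `consensus_shared_modules` merges them by single-linkage
on member overlap; the merged unions are what the pipeline reports as
the shared modules, and what the recovery benchmarks score against the
planted truth. Module-level Venn counts use exact member-set equality by
default with a Jaccard mode (τ = 0.8) available, since partial overlap
makes "the same module" a matter of definition; gene-level overlaps
intersect per-population unions of validated-module members and satisfy
inclusion–exclusion identities exactly.

Enrichment of shared genes is a one-sided hypergeometric upper tail per
user-supplied gene set, restricted to a stated universe, with
Benjamini–Hochberg q-values.

## GSVA arm

Per gene, expression is mapped to a kernel CDF across samples (Gaussian
kernel, bandwidth s_g/4; empirical CDF available for counts-like data).
Within each sample, genes are ranked by that score and the walk
statistic |p/2 − rank|^τ (τ = 1) weights a KS-like random walk down the
ranking; max-difference scoring (maximum positive deviation plus maximum
negative deviation) bounds every score in [−1, 1] and produces the
characteristic bimodal score distribution. Rank ties break by gene id
after sorting genes canonically, making scores invariant to gene and
sample order of the input. Sets are filtered to 10–500 genes after
intersection with the expression matrix (common practice; the filter is
configurable). Differential pathway activity reuses the moderated-t
machinery on the score matrix with BH correction. A test pins the walk
to an independent straight-line re-implementation at 1e-8.

## Synthetic generator

The generator emulates the *structure* the pipeline assumes, not any
real dataset: 3 populations (labels Afr/Hisp/White by default, matching
the AD study design it mimics; `AD_COHORT_PRESET` provides the real
cohort sizes including the 85/1136 imbalanced one), 600 genes by default
(the per-tissue imputable-gene scale of a few thousand, reduced for
speed), 13 brain-tissue labels available, a preferential-attachment
network with mean degree ~4, and expression = per-gene baseline +
sex/age/latent-factor contributions + case-only mean shift + unit
Gaussian noise. The latent factors are recorded as `pc_1..pc_4` in the
sample table, so adjustment can remove exactly the structure that was
injected.

The planted module (default: 10 genes, 0.8 SD effect) is wired into a
connected, fairly dense subgraph (random spanning path + extra edges at
rate 0.3). Per population the effect falls on a 4-gene sliding window of
the members with adjacent windows overlapping by one gene. Fully
disjoint effect subsets would make every cross-cohort evaluation
score exactly null — a module discovered in one population would carry
zero signal anywhere else — which contradicts the premise being
emulated (shared pathways, partially different genes); the 1-gene
window overlap is the minimal sharing that keeps the bridge physically
present. Window positions, sizes and explicit subsets are configurable,
including fully disjoint ones for sensitivity analysis.

What the generator does **not** emulate: linkage disequilibrium and
ancestry-specific eQTL architecture, family structure, imputation-model
uncertainty, correlated co-expression beyond the planted factors, or
realistic PPI topology beyond a scale-free degree distribution. Passing
the recovery benchmarks therefore certifies the pipeline's mechanics
and calibration, not performance on real cohort data.

## Problem sizes and determinism

Benchmarks run at: 10 simulated studies for module recovery (600 genes,
300 samples × 3 populations each), 200 random modules × 1000
permutations for null calibration, 2000 genes for hyperparameter
recovery, 20 replicates of 200 genes × 300 samples for GSVA detection —
sizes chosen so the whole suite completes in a couple of minutes on one
CPU while keeping the binomial/KS margins meaningful. Every stochastic
component takes an explicit seed (numpy `default_rng`); identical
seeds give byte-identical output tables, which an end-to-end test
asserts. Re-running any stage from the manifest reproduces its outputs.

## Known limitations

- The greedy search is a heuristic; it can miss modules whose best seed
  is buried (no simulated annealing or exhaustive variant).
- Edge confidence scores filter the network but do not weight the
  objective (no edge-weighted search).
- Cross-tissue runs pool modules with tissue labels kept; no
  cross-tissue multiplicity correction is applied.
- No kinship correction: family-structured cohorts will inflate the
  effective sample size.
- The GSVA implementation covers the standard scoring path (gaussian/
  ecdf kernels, τ, max-difference); ssGSEA/PLAGE/z-score variants are
  not provided.
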