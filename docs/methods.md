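# Methods

This note documents the models and procedures `survfit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical conventions adopted where more than one
reasonable choice existed.

## 1. Survival fitness from barcode counts

### Model

A randomly barcoded transposon insertion (RB-TnSeq) library is a pool of
insertion mutants, each tagged by a unique DNA barcode whose read count in
an amplicon-sequencing sample is proportional to the strain's abundance in
the pool. In a *survival* experiment the pool is exposed to a challenge
condition with no growth (here: anoxic groundwater-like incubations varying
exposure time, pH/contamination level, or glucose concentration), then
subcultured back into rich medium for outgrowth. Barcodes are sequenced
before (reference) and after (outgrowth), and the fitness read-out reflects
differential *survival* during the challenge rather than differential
growth rate.

For strain *s* with pooled reference count `n_ref` and outgrowth count
`n_out`, the raw strain fitness is

    f_s = log2( (n_out + ψ) / (n_ref + ψ) )

with pseudocount ψ (default 0.1) keeping zero counts finite. Gene fitness
is the weighted average over the gene's included insertion strains,

    f_g = Σ_s w_s f_s / Σ_s w_s ,
    w_s = 1 / ( 1/(1 + n_ref) + 1/(1 + n_out) ) ,

the inverse of the approximate variance of a log ratio of two counts, so
poorly covered strains contribute little. Per-sample gene fitness values
are then normalized by subtracting the median gene fitness within each
scaffold (chromosome or plasmid), and replicate challenge vials of a
condition are averaged (unweighted — they are equal-status vials) after
normalization.

### Why median normalization, and what it assumes

Two systematic offsets contaminate the raw log ratio: (i) the reference
pool is the sum of several reference samples, so its depth differs from a
single outgrowth sample's by a constant factor; (ii) sequencing measures
*relative* abundance, so when part of the pool dies the survivors' relative
abundances all rise — a compositional offset of
`−log2(Σ_j b_j 2^{e_j})` shared by every strain. Both offsets are constant
within a sample, so subtracting the per-scaffold median removes them
exactly, under the assumption that the median gene on each replicon is
fitness-neutral. This assumption fails if a majority of genes on a
scaffold respond to the condition; the synthetic-data defaults (below) keep
the planted-effect fraction well under half for this reason, and the same
caveat applies to real libraries. Per-scaffold (rather than global) scope
guards against replicon-level artifacts such as plasmid copy-number shifts;
scaffolds carrying fewer than 5 scored genes fall back to the global median
with a warning. The smoothed, insertion-position-dependent normalization
used by the established BarSeq analysis framework is deliberately
simplified to median centering here; position effects enter only through
the QC window.

### Quality control

Defaults, all configurable via `FitnessConfig`:

| parameter | default | rationale |
|---|---|---|
| pseudocount ψ | 0.1 | finite log ratios; negligible for counts ≫ 1 |
| central window | [0.1, 0.9] of gene length | terminal insertions often leave function intact |
| min reference reads / strain | 3 | a ratio needs a measurable denominator |
| min reference reads / gene | 30 | gene estimates need aggregate support |

Excluded strains and genes carry reason codes
(`non_central_insertion`, `low_reference_count`,
`low_gene_reference_reads`) in a QC report; they are flagged, never
silently dropped.

## 2. Gradient screen

Along an ordered gradient (time 0.5→48 h, pH 7.4→3.9, glucose 0→5 mM) the
screen computes, per gene:

- **Δfitness** between the two endpoint conditions (by default the
  extremes; other pairs, e.g. 5 mM vs 1 mM glucose, are selectable), which
  is exactly antisymmetric in the endpoints;
- **R²** of an ordinary least-squares second-order polynomial fit of the
  fitness trajectory over all gradient conditions.

A gene is a hit iff |Δ| ≥ cutoff (default 1.5 log2 units, boundary
*inclusive*) **and** R² ≥ 0.50. The polynomial filter removes erratic
single-point excursions that produce a large endpoint difference without a
coherent trend. Single-condition screens (e.g. a mild 30-minute challenge)
apply only the magnitude threshold to the fitness values themselves.

Conventions: R² requires ≥ 4 finite points (3 parameters + 1 residual
degree of freedom); fewer points fail the filter with reason
`insufficient_points`. R² is clipped to [0, 1]. A zero-variance trajectory
gets R² = 1 if the fit is exact and 0 otherwise — this convention can never
decide a hit, since a gene passing |Δ| ≥ 1.5 cannot be constant. Genes with
a missing endpoint value are flagged `missing_endpoint` and excluded from
the fit rather than imputed. Hit sets are monotone non-increasing in both
the cutoff and the R² floor.

## 3. Pangenome statistics

Input is a binary ortholog presence/absence matrix (clusters × genomes);
ortholog clustering itself is upstream and out of scope. On a matrix with
N genomes:

- **Partition.** Core = prevalence N; cloud = prevalence/N ≤ 0.15; shell =
  the rest. The cloud boundary applies *without rounding genome counts*:
  at N = 75, 11 genomes (14.7%) is cloud and 12 (16%) is shell. Core +
  shell + cloud = observed pangenome size, always.
- **Accumulation curves.** For a random genome ordering, the running
  intersection (rarefaction, toward the core) and union (amplification,
  toward the open pangenome) sizes; averaged over orderings. All N!
  orderings are enumerated exactly for N ≤ 7, otherwise 100 seeded random
  permutations by default. The n = N endpoints are order-independent.
- **Openness.** Heaps-type power law G = c·N^γ fit on log G = log c +
  γ·log n by least squares *with the intercept fixed at the core size c*,
  because c is the core genome size, not a free parameter:
  γ = Σ log(G(n)/c)·log n / Σ (log n)². γ = 0 is a closed pangenome; values
  toward 1 indicate an open one.
- **Full-size estimate.** Chao1 lower bound N1 = Nobs + F1²/(2·F2) from
  singleton (F1) and doubleton (F2) cluster counts. When F2 = 0 the
  bias-corrected form Nobs + F1(F1−1)/2 is used — a documented convention,
  since the plain formula is undefined there. N1 ≥ Nobs with equality iff
  F1 = 0.
- Subsetting a matrix to a genome group (a phylogroup) drops clusters
  absent from every retained genome before any statistic: a cluster
  observed nowhere in a group is not part of that group's pangenome.

## 4. Prevalence classes and integration

Focal-strain genes are joined to the pangenome via their cluster id;
prevalence is the cluster's row sum. Classes over [1, N]:

    singleton (1) < cloud (≤15% of N) < low_shell < high_shell < core (N)

Singleton is tested before cloud so prevalence-1 genes are never labeled
cloud. The low/high shell boundary is genomes strictly below 80% of N
(59 of 75), configurable either as a count or a fraction. Each gene's
genomic location (chromosome, genomic island, plasmid) is an *input*
annotation — island prediction is out of scope. The cross-tabulation of
hits by direction × location × prevalence class conserves margins exactly;
genes missing context are reported as `unknown`, never dropped.

## 5. Synthetic data generator

The generator exists so that every estimator above can be validated by
parameter recovery on data with known truth; it emulates the *statistical*
structure of a survival-fitness experiment, not the sequencing chemistry.

- **Library.** Genes allocated across a chromosome + 3 plasmids (relative
  gene counts 3558/496/110/5); strains per gene drawn from a floored
  negative binomial (configurable mean/dispersion, or deterministic);
  insertion positions central (10–90%) with probability
  `central_fraction`; unique random 20-nt barcodes.
- **Baseline abundances** are log-normal (σ = 0.5 by default) — real
  barcoded libraries are uneven, and an uneven baseline exercises the
  weighting scheme.
- **Challenge.** Each gene's planted effect is a quadratic in the gradient
  value (log2 units, clipped at ±8); the quadratic form matches what the
  screen's polynomial filter assumes smooth responses look like, and
  constant and linear effects are special cases. Post-challenge strain
  abundances are baseline × 2^effect, renormalized to sum to 1 — modeling
  that sequencing a survivor pool measures composition, and deliberately
  creating the compositional offset the normalization step must remove.
- **Sequencing.** Each sample is one multinomial draw at the configured
  depth (default 10⁶ reads), so column sums equal the depth exactly.
  Defaults mirror the experimental design: 5 replicate challenge vials per
  condition, 6 pooled reference samples. No read-level error, PCR bias, or
  index hopping is modeled — so passing recovery tests demonstrates
  estimator correctness under multinomial counting noise, not robustness
  to amplification artifacts.
- **Pangenome.** Core clusters present everywhere; accessory clusters
  present per genome independently with Beta-distributed probabilities
  (default Beta(0.3, 1), a rare-heavy spectrum giving a large cloud),
  conditioned on each cluster appearing in ≥ 1 genome (exact
  zero-truncated-binomial resampling of empty draws). A deterministic
  *nested* construction is also provided in which genome n carries clusters
  1..round(c·n^γ): adding genomes in index order reproduces the target
  power law exactly (the order-averaged curve cannot equal an exact power
  law, so the construction's guarantee is defined for index order, exposed
  via `cumulative_sizes`).
- **Seeding.** One integer seed drives everything through
  `numpy.random.SeedSequence` spawning (library / baseline / reference
  draws / outgrowth draws are separate streams), so outputs are
  reproducible byte for byte and any sub-simulation can be regenerated
  independently.

The library size of the real focal strain's library is not published;
defaults (100–200 genes × ~10 strains in tests, configurable) are scaled to
make desk-scale validation fast while keeping per-strain counts in the
regime where the weighting matters. Validation problem sizes (depth 10⁶,
20 replicate simulations for recovery, 10 planted trends among 200 nulls
for the screen, 1000 random matrices for the partition identities) were
chosen as the smallest sizes at which the checked tolerances are
informative.

## 6. Known limitations

- Median normalization assumes a mostly-neutral gene set per scaffold (see
  §1); screens where most genes respond would need external spike-ins.
- No significance statistic accompanies gene fitness; the screen is
  threshold-based by design, and no multiple-testing correction applies.
- The openness fit inherits the amplification curve's dependence on the
  permutation sample for N > 7; with the default 100 permutations the
  Monte-Carlo error on γ is well below the fit's systematic sensitivity to
  the fixed-intercept choice.
- The Chao1 estimate is a lower bound, and a poor one when the singleton
  count is inflated by annotation fragmentation — an input-quality issue
  upstream of this package.
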