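# Methods

`milletgs` implements the analysis workflow of a CMS-based single-cross
hybrid breeding programme of the kind used for pearl millet in India: inbred
B-lines (maintainers, used as females through their sterile A-line
counterparts) and R-lines (restorers, used as males) are genotyped by
reduced-representation sequencing, F1 hybrid genotypes are projected from
the parents, multi-environment trial data are reduced to entry BLUPs, and
RR-BLUP genomic prediction is evaluated under four training schemes. This
note records the models, the numerical choices, and what the synthetic data
do and do not capture.

## Genotype calling and marker QC

Genotype calls are made per (sample, site) from allele read counts:

* **homozygous** — total depth ≥ 5 and the top allele's frequency > 0.9
  (strict);
* **heterozygous** — total depth ≥ 5, the two most frequent alleles jointly
  account for ≥ 90% of reads, each has ≥ 2 reads and each has frequency
  > 0.2 (strict);
* otherwise **missing** (a value, not an error).

Ties in read counts are broken by allele name; the thresholds themselves
make the call order-independent, which is property-tested.

Marker filters retain sites that are biallelic, show ≥ 2 genotype classes,
have a heterozygote fraction among called samples ≤ 0.10, a minor allele
carried (het or hom-minor) by ≥ 5 samples, and a call rate ≥ 0.20. Every
boundary is read literally from the rule it implements and unit-tested;
comparisons run on integer counts because rate arithmetic in floating point
misclassifies exact boundaries (e.g. 1 − 0.8 < 0.2 in doubles). MAF is
(2·hom-minor + het) / (2·called); downstream analyses use markers with
MAF > 0.05 (strict).

Missing calls are filled by a deliberately naive, clearly-labelled
imputation stand-in: a seeded draw from the marker's observed genotype-class
frequencies (or the modal class). It never introduces an unobserved
genotype. Haplotype-phasing imputation is out of scope; analyses that need
properly imputed data should supply externally imputed files.

## F1 projection

Hybrid dosages on the 0–2 scale follow three rules — identical homozygous
parents pass their call through, opposite homozygotes give a heterozygote,
and any heterozygous parent contributes the mean of the two parental
dosages. All three are jointly equivalent to the midpoint rule
(p₁ + p₂)/2, which the implementation uses directly (and verifies by
enumeration over all nine integer pairs). A missing parent call projects to
a missing hybrid call; the intended order of operations is imputation before
projection, which makes that case rare. Projected dosages may be half-integer
and are kept real-valued; VCF GT cannot encode them, so the dosage matrix is
the canonical output format and a DS-field VCF writer is provided.

## Phenotype model

Plot values are modelled with genotype (G), location (L), G×L, replicate
and block all random, plus an i.i.d. residual. Replicate and block are
nested within location by default (replicate:location,
block:replicate:location) because that is the physical layout; a flat
coding is available since the factor list could equally be read unnested.
Missing plot values are dropped row-wise per trait.

REML estimation uses Henderson's mixed-model equations with
average-information updates and EM warm-up/fallback. Components are kept
nonnegative with a floor of 1e-8 × var(y); an active-set step pins
boundary components with negative gradient so they cannot stall the free
ones. Convergence is |Δ log-likelihood| < 1e-8 with a 200-iteration cap.
The solver is validated three ways: the MME log-likelihood and score agree
with a direct dense-V implementation to ~1e-14; balanced designs reproduce
the expected-mean-squares (ANOVA) estimators to machine precision; and a
seeded 240-plot fixture matches an independent R lme4 fit to about seven
significant digits (components, intercept, log-likelihood and BLUPs, frozen
in the test suite).

Entry-mean (broad-sense) heritability is

    H² = V_G / (V_G + V_G×L / N_L + V_ε / (N_R · N_L)),

with N_L locations and N_R replicates; location, replicate and block
variance do not enter. Variance-partition reports fold replicate and block
variance into the residual bucket. H² is reported as missing when all three
entering components are zero.

Mid-parent heterosis per hybrid is (Y_H − MP)/MP with
MP = (Y_female + Y_male)/2. Because a ratio of zero-centred BLUPs is
ill-defined, the default evaluates it on grand-mean-restored values
(intercept + BLUP), which preserves the familiar percentage interpretation;
a raw-BLUP mode exists for sign checks, and hybrids with a non-positive
mid-parent are flagged and excluded from medians. Both modes share the same
numerator, which is tested.

## RR-BLUP and the four training schemes

The marker model y = μ + Σ xᵢgᵢ + e gives every marker a common effect
variance, i.e. ridge regression with λ = σ²_e/σ²_g. λ is estimated by
restricted maximum likelihood through the eigenvalue profile of the
column-centred marker kernel (the centred kernel annihilates the intercept
direction, so the restricted spectrum is available directly); the 1-D
profile over log λ is optimised on a grid refined by bounded scalar
minimisation. μ is the training mean and effects are the ridge solution on
centred dosages — solved in the entry × entry kernel space when markers
outnumber entries and in marker space otherwise; the two are algebraically
identical and tested to 1e-8.

Schemes, with accuracy defined as the mean Pearson correlation over the
five folds of a repetition (Spearman available):

* **M1** inbred-only: five-way split of the inbreds; each sub-prediction
  trains on 4/5 of them and predicts *all* hybrids.
* **M2** hybrid-only: conventional five-fold CV on the hybrids.
* **M3A**: M2 with every inbred (absolute, jointly-scaled values) appended
  to each training fold.
* **M3B**: M3A after centring inbred and hybrid values by their own
  population means (computed over all phenotyped entries of the
  population). Centring the test population is an affine shift and leaves
  the measured correlation unchanged.

Twenty repetitions by default; marker subsets (2⁶ … 2¹⁴ plus "all",
clipped to availability) are drawn uniformly without replacement, fresh per
repetition, and shared across schemes within a repetition so scheme
contrasts are paired. Fold remainders are spread one per fold. Scheme
contrasts use a paired two-sided t-test by default (the design is paired);
Welch's test is available. Degenerate cases: identical accuracy vectors
give p = 1, an exact constant shift p = 0, a single repetition a missing p.

Hold-out-parent validation removes every hybrid sharing either of a chosen
(B-line, R-line) pair from the training pool, trains on 4/5 of the
remainder and predicts the excluded hybrids. Exhaustive prediction projects
and scores every cross in a factorial plan chunk-wise so the full hybrid
matrix is never materialised. The production-possibility frontier is the
non-dominated set for a maximise/minimise trait pair (no other hybrid with
≥ yield and ≤ flowering time, one strict), computed by a sweep and checked
against an O(n²) dominance oracle.

## Synthetic data: what it emulates, and what it does not

Founder pools are fully inbred lines with per-marker alternate-allele
frequencies drawn uniformly from a MAF band, independently per pool; an
optional `pool_divergence` fraction flips the common allele between pools
to model strongly differentiated heterotic groups. Traits are additive +
dominance architectures: value = baseline + Σ a(x−1) + d·1[x=1], so fully
inbred parents collect no dominance and directional dominance (d ∝ |a|) is
the knob that generates mid-parent heterosis in the hybrids. Field books
follow the emulated trial: 4 locations × 2 replicates of 15-plot incomplete
blocks, each holding 2 repeated controls and 13 experimental entries, with
location, G×L, replicate, block and residual effects drawn at configured
SDs. Incomplete blocking is a *random* allocation of entries to blocks —
the downstream model consumes only the factor labels, so the generating
alpha-lattice algorithm is not reproduced. An option segregates hybrid and
inbred plots into separate blocks, default off. Trait units are abstract;
no attempt is made to mimic kg/ha magnitudes.

Not emulated: read-level sequencing error, linkage disequilibrium beyond
what shared parentage induces (markers are exchangeable given the pool
frequencies), spatial field trends, multi-year effects, epistasis, and
cytoplasm effects of the CMS system. Passing tests therefore demonstrate
the statistical machinery under the assumed variance structure, not
robustness to map-structured LD or spatial autocorrelation in real trials.

## Problem sizes and seeds

All stochastic steps run off explicit integer seeds
(`numpy.random.default_rng` / `SeedSequence` spawning per repetition);
fixing the seed fixes every table bit-for-bit, which is tested. The
phenotyped population mirrors the emulated study (4 locations × 2
replicates, ~300 hybrids plus ~40 inbred parents); genotyped founder pools
and marker panels default to tens of lines and a few thousand markers,
which is where the estimators' behaviour stabilises, while the full
192 × 192 factorial (36,864 crosses) is exercised structurally in
projection and counting. The heritability-recovery experiment uses true
components (V_G, V_G×L, V_ε) = (1, 0.24, 0.611), which place the
entry-mean H² at 0.88 under the 4 × 2 design.

The cross-validation null is evaluated with a *fresh* permutation of the
trait per repetition. A single fixed permutation retains a chance
association of magnitude ≈ 1/√(number of parents) with the family
structure, which cross-validation consistently detects (≈ 0.1 mean r at 80
parents); that is a property of the germplasm's relatedness, not a defect
of the model, and the per-repetition permutation is the standard
permutation-test null.

## Known limitations

* The REML solver is dense; it is comfortable to a few thousand mixed-model
  equations (≈ 3,000 plots with G×L) but not built for very large trials.
* The naive imputation stand-in ignores linkage entirely; summary
  statistics computed after it are not comparable to haplotype-imputed
  data.
* Dominance enters the simulator but not the prediction model — RR-BLUP is
  additive, which is exactly what makes the M3A bias reproducible.
* GCA/SCA decompositions, Bayesian marker models and pedigree GBLUP are out
  of scope.
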