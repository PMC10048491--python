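# Methods

`herdgwas` implements a genome-wide association workflow for milk-production
traits in a small, strongly structured dairy-cattle population, together
with a synthetic-data generator that reproduces the statistical features of
such a herd so that every stage can be validated against known truth.

## The association model

For each trait-lactation cell the per-variant test is an ordinary
least-squares regression

```
y = ps + f* + s* + by* + bs* + cy* + cs* + ac* + g·beta + e
```

where `ps` is the population-stratification cluster (categorical, always
eligible), the starred terms are optional fixed effects — farm, sire, birth
year, birth season, calving year, calving season and age at first calving in
days (continuous) — and `g` is the additive minor-allele dosage (0/1/2).
Rows with a missing response, covariate or genotype are dropped listwise per
variant, so the analysis n differs across lactations exactly as it does in
305-day milk-recording data. `beta` is the allele-substitution effect of the
minor allele in trait units; its p-value comes from a two-sided t test on
the residual degrees of freedom.

An optional effect enters a trait's model only when adding it alone to the
stratification-only null lowers the Gaussian OLS AIC by at least 10
(`delta AIC <= -10`). Effects are tested singly, never stepwise; the AIC is
`n ln(2*pi*RSS/n) + n + 2(k+1)` with the RSS floored at 1e-12 against exact
fits. Collinear design columns are pruned deterministically left-to-right.

### Numerical core

The scan residualizes both the response and all complete-genotype dosage
columns against an orthonormal basis of the covariate design
(Frisch–Waugh), reducing each variant to a handful of vector operations;
variants with missing genotypes fall back to an explicit least-squares
solve on their complete rows. The two routes agree with the closed-form
normal-equations solution to ~1e-10 on small fixtures and this equivalence
is pinned by tests.

## Cohort and phenotype construction

* Analysis cohort: iterated removal of cows belonging to any farm, sire or
  birth-year group with fewer than 20 members, run to a fixed point because
  removals shrink other groups. The operation is idempotent.
* Records: only full lactations (>= 270 days in milk) contribute.
* Contents: fat% and protein% are `100 * yield / milk yield` per lactation.
* Outliers: per trait-lactation column, values strictly outside
  mean ± 3 SD are set missing; mean and SD are computed once per column on
  the post-cohort data (the filter is applied per column rather than pooled
  across lactations — lactation means differ, so pooling would bias the
  bounds).
* Lactation mean (LAm): present only when all three single-lactation values
  of the trait survived; LAm models use the first lactation's calving
  covariates, which the record data defines for every cow in the cohort.

## Population stratification

Relatedness clusters come from complete-linkage agglomeration on the
pairwise identity-by-state distance `1 - IBS/2`, constrained by the
pairwise population concordance (PPC) test: among sites where a pair is
either both-heterozygous (IBS2-het) or opposite-homozygous (IBS0), the
IBS2-het count is Binomial(n, 2/3) under panmixia for any allele
frequency. The merge constraint uses the one-sided (deficiency) exact
binomial p-value at cutoff 1e-5: a *deficit* of shared heterozygotes marks
a pair drawn from different populations, whereas an excess merely marks
relatives, who must of course stay mergeable. (`ppc_test` also exposes the
two-sided alternative.) Merges proceed in ascending distance with ties
broken by the smallest member index, so the assignment is deterministic and
equivariant under row permutations.

## Genomic control

The inflation factor is `lambda = median(chi2)/0.4549` over a chromosome
class; the X chromosome is corrected separately from the autosomes, and
lambda is estimated per trait (with per-class reports). When
`lambda_obs > 1.2`, every chi-square in the class is multiplied by
`1.2/lambda_obs` and p-values are recomputed — the classic uniform
rescaling, chosen over quantile matching because it is the simplest
transform that reaches the target exactly and provably preserves variant
ranking. Classes at or below the target are left untouched: correction
never makes a p-value smaller.

## Significance thresholds and QTL regions

The effective number of tests M is the survivor count of greedy LD pruning
(windows of 500 variants, step 100, removing the lower-MAF member of every
pair with r² > 0.6; position ties drop the later variant; removals persist
across windows, and pairs are processed in ascending index order for
determinism). Thresholds are `-log10(alpha/M)` for alpha = 0.01 / 0.05 /
0.1 (highly significant / significant / suggestive). Pairwise r² is the
squared dosage correlation over pairwise-complete calls; D' comes from
two-locus EM haplotype-frequency estimation (tolerance 1e-8, <= 1000
iterations).

QTL regions are defined in two stages on the corrected statistics pooled
across all traits: (1) suggestive variants on a chromosome form one coarse
group while consecutive gaps stay within 2.5 Mb, counting each variant once
across traits, and groups with fewer than three suggestive variants are
discarded; (2) within a surviving group, the region around each trait's
top SNP (smallest p; position breaks ties) grows by repeatedly absorbing
suggestive variants within 500 kb of the current bounds. The core is the
member span; display bounds add 100 kb per side (floored at 1). Growth is
measured from the region bounds, not pairwise to the top SNP. Regions with
identical bounds in one group are merged and carry one top-SNP entry per
trait.

## GRM and REML heritability

The genomic relationship matrix is the allele-frequency-standardized
cross-product `G = ZZ'/(2 Σ p_i(1-p_i))` with per-marker mean-centered
dosages, mean imputation of missing calls and monomorphic markers excluded.
Heritability is estimated under `y ~ N(Xb, σ²_g G + σ²_e I)` by restricted
maximum likelihood: one symmetric eigendecomposition of G turns every
V-solve into diagonal arithmetic; updates are average-information steps
with an expectation-maximization fallback whenever an AI step leaves the
parameter space or decreases the restricted likelihood. Components are
floored at 1e-8; convergence is `|Δ logL| < 1e-6` within 200 iterations;
SE(h²) comes from the inverse AI matrix by the delta method.

The REML fixed design reuses the trait's selected covariates *except* the
sire effect: family structure is exactly what the GRM models, and fitting
sire as a fixed effect absorbs the between-family genetic variance,
biasing h² down by roughly a quarter in half-sib designs. The association
scan keeps sire (conservative for structure); the variance-component model
must not.

## The synthetic herd

Defaults describe the target design: 2000 cows on 8 farms, descended from
37 sires, born across 10 years, with three 305-day lactations whose
retention declines (0.95 / 0.82 / 0.80 conditional per lactation, matching
the attrition pattern of field milk-recording data).

**Genotypes.** Each chromosome is cut into LD blocks with exponential
lengths (mean 100 kb). Every gamete copies one haplotype from a pool of 20
founder haplotypes per block: within a block alleles travel together,
across blocks picks are independent. Founder alleles are laid out as nested
carrier sets along a per-block founder ordering — a star-genealogy pattern
giving D' near 1 and substantial r² between block neighbours, as expected
in a breed with effective population size around one hundred — while a
fraction `ld_noise = 0.3` of variants re-draw their carrier set and
decouple, so r² within blocks is high but not uniform. Sires are
represented by two founder-index gametes, giving paternal half-sib families
elevated IBS; optional discrete subpopulations diverge by Balding–Nichols
sampling at a configurable Fst and can shift trait means to create
confounding. Planted QTL pin the founder carrier count to the requested
frequency and always ride the block haplotypes so they have LD neighbours.
Missing calls are masked completely at random at the configured rate.

**Phenotypes.** Milk yield (kg) and fat/protein content (%) are simulated
per lactation as mean + covariate effects + genetic value + noise; fat and
protein yields are content × milk, which reproduces the classic correlation
pattern (yields strongly correlated within a lactation; the two contents
nearly independent). The genetic value is planted QTL effects plus a
polygenic term built from 1000 random markers, orthogonalized and scaled so
that the realized variance ratio equals the configured h² exactly (defaults
0.40 / 0.50 / 0.60 for milk, fat%, protein%, the middle of the range
reported for such traits); the lactations share one genetic value, which
produces moderate cross-lactation correlations without a full repeatability
model. Covariate effect magnitudes are in trait-SD units (farm 0.5, birth
year 0.25, seasons 0.1–0.15). An optional "X" chromosome is an ordinary
diploid chromosome carrying the label only, so the per-class correction
path is exercised; dosage compensation is not modeled.

**What the generator does not emulate.** Genotype imputation error,
selection, assortative mating, multi-generation pedigrees, dominance and
epistasis, lactation-curve shapes, and non-random missingness. Passing
recovery tests therefore show the estimators are correct under an additive
model with block LD and half-sib structure — not that real imputed WGS data
meet those assumptions.

## Problem sizes used in validation

The validation suite scales the study design down so the full pipeline runs
in minutes: recovery experiments use 2000 cows × 50,000 variants on five
25-Mb chromosomes (10 replicate seeds) with three planted milk-yield QTL of
0.3/0.4/0.5 phenotypic SD at MAF 0.2–0.4 and h² = 0.4; the null
calibration uses 2000 unrelated cows × 20,000 variants. Chromosome length
is scaled with the panel so that the variants-per-LD-block count stays in a
realistic regime (~40; dense WGS panels carry hundreds), since QTL-region
formation depends on that density, not on absolute genome size. Threshold arithmetic is checked at the published count of
642,791 independent variants, and the genomic-control contract on 100,000
null chi-square statistics inflated by 1.5.

## Known limitations

* Single-component GREML weights each causal variant's contribution by its
  local LD relative to the panel average. Major QTL that sit on common,
  strongly tagged haplotypes — which is precisely what makes them
  recoverable as QTL regions — are therefore up-weighted, and ĥ² runs a few
  points above the simulated value in scenarios where such QTL carry a
  large share of the genetic variance (conversely, poorly tagged causal
  variants pull it down). This is a property of the one-component model,
  which the pipeline deliberately retains; LD-stratified GRM partitioning
  would remove it but is out of scope.
* The PPC clustering is O(n³) in individuals with an exact binomial per
  pair; it is intended for cohorts of a few thousand, and the test suite
  exercises it at a few hundred.
* Genomic control rescales uniformly; confounding that inflates the tail
  more than the median is only partially removed.
* The REML solver fits a single genetic variance component; bivariate
  models and genetic correlations are out of scope.
* D' from two-locus EM is undefined for monomorphic pairs and returned as
  NaN rather than guessed.
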