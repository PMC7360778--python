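# Methods

## The problem

Mendelian randomization (MR) treats genetic variants as instrumental
variables for an exposure, on the argument that meiosis randomizes
genotypes with respect to environmental confounders.  In samples of
unrelated individuals that argument can fail in three ways: *dynastic
effects* (the expression of parental genotype in the parental phenotype
directly affects the offspring's outcome, opening a path from the
offspring's inherited allele to the outcome that does not run through the
offspring's exposure), *assortative mating* (spouses matched on phenotype
induce cross-trait genetic correlations in their children), and *residual
population stratification* (allele-frequency differences between
subpopulations correlated with phenotype differences).  All three are
family-level confounders; conditioning on family removes them, because
genotype differences *between siblings*, or between an offspring and the
expectation given its parents' genotypes, are pure meiotic randomness.

`sibmr` implements the within-family estimators, the summary-data MR layer
on top of them, and a forward-in-time family simulator that generates
exactly these confounding structures so that the designs' false discovery
rate (FDR), power and bias can be measured.

## Structural model

For individual *i* in family *k*, with per-SNP additive dosages
`g_{k,i,j}`, individual confounder `C_{k,i}` and family-level confounder
`f_k`:

    x_{k,i} = gamma_0 + sum_j gamma_j g_{k,i,j} + gamma_2 C_{k,i} + f_k + v_{k,i}
    y_{k,i} = beta_0  + beta_1 x_{k,i}          + beta_2 C_{k,i}  + f_k + u_{k,i}

`beta_1` is the causal effect of interest.  In the simulator `f_k` is
realized through the dynastic path (the parents' exposures acting on the
offspring outcome) and, optionally, a deme offset.

### Variance-share parameterization

All phenotypes are standardized (theoretical mean 0, variance 1) and every
structural path is specified as the fraction of variance it explains:

| parameter | meaning | default |
|---|---|---|
| `v_gx` | exposure variance explained jointly by the loci | 0.1 |
| `b_xy` | outcome variance explained by own exposure (causal path) | 0 |
| `b_ux` | offspring-outcome variance explained by the combined parental exposure (dynastic path) | 0 |
| `c_x`, `c_y` | exposure/outcome variance explained by the individual confounder | 0 |
| `n_snps` | independently segregating biallelic loci, equal effects | 90 |
| `allele_freq` | effect-allele frequency per locus | 0.5 |
| `assort_rho` | target spousal exposure correlation | 0 |

The coefficient applied to a standardized source is the square root of its
share, so `b_xy = 0.01` means a standardized slope of 0.1 and "1% of
variance explained".  The residual scale subtracts both the shares and the
analytic covariance cross-terms (e.g. the exposure and the confounder are
correlated sources of the outcome; the offspring genotype is correlated
with the parental exposure sum through inheritance, with parent-offspring
correlation 1/2 under random mating), so the theoretical phenotype
variance is exactly 1.  Under assortative mating the cross-term correction
uses the random-mating values and is therefore approximate; empirically
the sample variances stay within a few percent of 1.

Ninety loci with equal effects and frequency 0.5 emulate a GWAS-scale
instrument set (the shape of the per-SNP effect distribution is a free
choice; equal shares `v_gx/n_snps` keep every instrument equally strong).
Loci segregate independently — with ~90 recombination events separating
human siblings, 90 loci are effectively unlinked — so no linkage map is
modelled.

### Meiosis and IBD

Each parent transmits one of its two allele copies per locus with
probability 1/2, independently across loci, parents and offspring; the
transmitted-copy indicators are stored.  A sibling pair therefore shares
0, 1 or 2 copies identical by descent (IBD) per locus with probabilities
1/4, 1/2, 1/4; the per-pair mean IBD proportion over L independent loci
has mean 1/2 and SD sqrt(0.125/L) — 0.0373 at L = 90.  The simulator is
validated against this closed form.

### Mating and stratification options

Assortative mating rank-matches mothers' exposures against fathers'
exposures plus Gaussian noise with variance `1/rho^2 - 1`, which yields a
realized spousal correlation of approximately `assort_rho`; one generation
of assortment is modelled (no multi-generation compounding).  Two-deme
stratification assigns each family to a deme, offsets the allele
frequencies by ±`freq_offset` and the outcome mean by `outcome_offset`
(centred), and mates within deme.

### Dynastic routing

By default the combined parental exposure (standardized sum of the two
parents' exposures) acts directly on the offspring outcome with share
`b_ux`.  A config switch (`dynastic_route="both"`) instead routes the same
signal into both the offspring exposure and outcome — a "child confounder"
reading of the same phenomenon.  Both produce the SNP-outcome confounding
that biases unrelated-sample MR; the direct-to-outcome route is the
default.

Horizontal pleiotropy is absent by default; an optional `pleiotropy` share
adds direct SNP-to-outcome effects with random balanced weights to
exercise the pleiotropy-robust estimators.  Its variance bookkeeping
ignores the (mean-zero, O(1/sqrt(L))) overlap with the exposure-genetic
component.

## Estimators

**Per-SNP associations** (`sibmr.assoc`):

* *unrelated* — OLS of phenotype on dosage, one sibling per family (the
  first by individual-ID order), HC1 robust errors;
* *sibling difference* — phenotype difference regressed on dosage
  difference through the origin (the difference equations contain no
  intercept; one is available for diagnostics only); every within-family
  pair enters as a pseudo-independent pair with family-clustered errors;
* *family fixed effects* — the within transformation (demeaning by
  family) followed by OLS, CR1 family-clustered errors.  With exactly two
  siblings per family this is algebraically identical to the sibling
  difference estimator (demeaning maps each member to ± half the
  difference), and the tests assert the identity to machine precision;
* *trio* — OLS of the offspring phenotype on offspring, mother and father
  dosages; the offspring's conditional coefficient is the within-family
  estimate, and the parental coefficients measure the dynastic signal.

Cluster-robust covariances use the CR1 finite-sample factor
`G/(G-1) * (N-1)/(N-K)` — the convention of the standard econometric
fixed-effects packages.  Single-SNP functions use a t reference with
G - 1 degrees of freedom; bulk per-SNP tables exported as summary
statistics use normal p-values.  Complete-case analysis per
SNP-phenotype; degenerate designs (constant genotype, no within-family
variation, collinear trio dosages, a single cluster) raise
`InestimableError` rather than returning silent zeros.

**Individual-level IV** (`sibmr.ivmr`): allele harmonization of external
weight tables (matching pairs pass, swapped pairs flip the weight sign,
irreconcilable pairs are dropped and reported; palindromic A/T and C/G
SNPs are kept but flagged), weighted polygenic scores, and 2SLS with
optional family fixed effects (all variables within-transformed before
estimation).  The first stage's cluster-robust F is reported; no
weak-instrument correction is applied.  Just-identified 2SLS equals the
reduced-form/first-stage ratio exactly, and FE-2SLS on two-sibling
families equals 2SLS on sibling differences — both asserted in tests.

**Summary-data MR** (`sibmr.summr`): Wald ratio (first-order SE
`se_y/|beta_x|`, the NOME convention; a second-order option adds the
exposure-side term), IVW (weighted least squares of `beta_y` on `beta_x`
through the origin; random-effects via multiplicative overdispersion,
`SE * max(1, sqrt(Q/(L-1)))`), MR-Egger (weighted regression with
intercept, SNPs oriented to positive `beta_x`, t reference with L - 2
df), weighted median (weight-interpolated 50th percentile of the ratios)
and weighted mode (weighted Gaussian-kernel density mode, Silverman
bandwidth scaled by a `bandwidth` parameter, default 1), with seeded
parametric-bootstrap SEs (default 1,000 replicates) for median and mode;
Cochran's Q; and a two-sided normal test (`p_diff`) for the difference
between two independent MR estimates.

**Shrinkage** (`shrinkage_sur`): for each SNP the total (no fixed effect)
and within-family slopes are estimated jointly on the same siblings; their
2x2 covariance comes from stacked estimating equations with scores summed
by family (a cluster sandwich, which is what makes the cross-equation
dependence from sharing the sample tractable — chosen over a classical
FGLS seemingly-unrelated-regression fit for testability).  Percent
shrinkage `100*(total - within)/total` gets a delta-method SE (validated
against a family-resampling bootstrap within 15% in the tests); SNPs whose
total slope is indistinguishable from zero (|t| < 1) are excluded from the
fixed-effect inverse-variance pooling and reported.

**Study designs** (`sibmr.study`): each design maps a cohort to one causal
estimate — per-SNP exposure and outcome associations by the design's
estimator, then IVW.  Designs are compared at equal family counts: the
unrelated design analyses one sibling per family, the sibling design both
siblings, the trio design one offspring per family with both parents.
FDR/power is the proportion of iterations with two-sided p < 0.05; bias is
the mean of (estimate - sqrt(b_xy)).  Per-cell seeds are spawned
deterministically from the base seed (numpy `SeedSequence`), so identical
grid specifications give identical results and any cell is reproducible in
isolation.  Inestimable iterations are logged, excluded from the
proportions, and accounted for (`used + excluded = requested`).

The split-sample workflow halves the families at random (seeded),
estimates SNP-exposure associations in one half and SNP-outcome
associations in the other (removing sample-overlap/weak-instrument bias),
repeats with the roles swapped, and combines the two estimates by
fixed-effect inverse-variance meta-analysis.

## Expected behaviour and what the tests show

Under the dynastic null (`b_xy = 0`, `b_ux > 0`), each SNP's unrelated
outcome association is `gamma_j * sqrt(b_ux/2)` (the offspring allele is
correlated 1/2 with each parent's genotype), so the unrelated IVW estimate
converges to `sqrt(b_ux/2)` — about 0.22 at `b_ux = 0.1` — and its FDR
approaches 1 as n grows.  The within-family designs remove the path: their
FDR stays at the nominal 5% and their estimates centre on `sqrt(b_xy)`,
at the cost of larger standard errors (roughly half the effective genotype
variance is between families).  The acceptance suite measures exactly
these quantities at the study's conditions (10,000-20,000 families, 90
SNPs, 100-500 iterations; these sizes are the study conditions, not
tuning knobs).

For the parameter-recovery check the grid uses `b_ux = 0.1` with no
individual confounding (`c = 0`): with `c > 0` the same-sample IVW design
carries a known finite-sample pull toward the within-OLS slope of order
(OLS offset)/F — about 0.005 at n = 20,000 here — which is a property of
same-sample summary MR, not of the estimators under test; the split-sample
workflow exists precisely to remove it.

What passing tests do **not** show about real data: the simulator draws
balanced nuclear families with complete data, equal per-SNP effects,
Gaussian phenotypes, Hardy-Weinberg parents and no linkage, genotyping
error, missingness, sibling interaction effects or multi-generation
assortment.  Real cohorts violate all of these to some degree; the
simulator establishes the designs' statistical properties, not empirical
effect sizes.

## Numerical choices and degenerate inputs

* Significance threshold fixed at p < 0.05 for the FDR/power definition;
  IVW p-values are two-sided normal.
* Outcome-side SEs of exactly zero (noiseless constructed data) are
  floored at 1e-150 so ratio weights stay finite; with identical ratios
  the pooled estimate is exact regardless of weights.
* Wald ratios with `beta_x = 0` are inestimable; IVW excludes such SNPs.
* Harmonization drops irreconcilable allele pairs and always reports the
  count; zero usable score SNPs is an error.
* Ties in the assortative-mating rank match are broken by stable sort.
* `hypothesis` property tests are derandomized; all bootstrap and
  Monte-Carlo procedures take explicit seeds.

## Known limitations

Binary outcomes are handled as linear probability models (matching
percentage-point effect reporting), not via logistic links.  Families with
more than two siblings are supported by the fixed-effects path (the
difference path enumerates all within-family pairs as pseudo-independent
pairs), but the simulator itself always generates two.  The shrinkage
meta-analysis assumes independent SNPs (instruments are expected to be
LD-pruned upstream).  No LD-aware estimators, MR-Lasso, outlier-removal
(MR-PRESSO-style) or Steiger filtering; no X-chromosome inheritance,
mutation or recombination maps.
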