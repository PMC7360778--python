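# sibmr — within-family Mendelian randomization

Mendelian randomization (MR) uses genetic variants as instrumental
variables to estimate the causal effect of an exposure on an outcome.  In
samples of unrelated individuals the instrument's independence assumption
can fail through **dynastic effects** (parents' phenotypes, expressions of
their genotypes, directly shaping their children's outcomes),
**assortative mating**, and **residual population stratification** — all
family-level confounders that inflate SNP-outcome associations and can
manufacture spurious "causal" effects.  Conditioning on family closes
these paths: genotype differences between siblings, or between an
offspring and the expectation given its parents' genotypes, are pure
meiotic randomness.

`sibmr` is a toolkit for epidemiologists and statistical geneticists who
want to run, or study the properties of, family-based MR:

* **Per-SNP association estimators** — unrelated-sample OLS, the sibling
  difference regression, family fixed effects (the within
  transformation), and trio regression adjusting for both parents'
  genotypes; CR1 family-clustered sandwich errors throughout.
* **Individual-level IV** — allele harmonization of GWAS weight tables,
  weighted polygenic scores, and 2SLS with optional family fixed effects
  and cluster-robust first-stage F.
* **Summary-data MR** — Wald ratio, random-effects IVW, MR-Egger,
  weighted median and weighted mode, Cochran's Q, a test for the
  difference between unrelated and within-family estimates, and
  total-vs-within SNP-association shrinkage via jointly estimated
  (seemingly unrelated) regressions.
* **A forward-in-time family simulator** — mother-father-sibling-pair
  cohorts with Mendelian transmission at 90 independent loci, a
  variance-share phenotype model, dynastic paths, assortative mating and
  two-deme stratification.
* **The simulation study** — false-discovery-rate, power and bias grids
  comparing the unrelated, sibling-FE and trio designs.

For the model, estimator and simulator details see
[docs/methods.md](docs/methods.md).

## The statistical core

For individual *i* in family *k*:

    x_ki = γ0 + Σ_j γ_j g_kij + γ2 C_ki + f_k + v_ki        (exposure)
    y_ki = β0 + β1 x_ki       + β2 C_ki + f_k + u_ki        (outcome)

`f_k` is a family-level confounder (dynastic effects, assortment,
stratification).  Unrelated-sample MR is biased because `g` and `f_k` are
correlated; the sibling difference `g_{k,1,j} − g_{k,2,j}`, the family
fixed effect (demeaning by family), or conditioning on parental genotypes
removes `f_k`.  The resulting per-SNP (γ̂_j, Γ̂_j) pairs feed any
summary-data MR estimator; the package pools them with IVW by default.

## Worked example

Simulate a null cohort with a dynastic path (no causal effect,
`b_ux = 0.1`, confounder shares 0.1) and compare the unrelated-sample
design with the within-family designs:

```python
from sibmr import SimulationConfig, simulate_cohort, run_cell

cfg = SimulationConfig(n_families=10_000, b_xy=0.0, b_ux=0.1,
                       c_x=0.1, c_y=0.1)
res = run_cell(cfg, designs=("unrelated_ivw", "sibling_fe", "trio"),
               iterations=20, seed=1)
print(res[["design", "fdr_power", "mean_bias"]].to_string(index=False))
```

```
       design  fdr_power  mean_bias
unrelated_ivw        1.0   0.211812
   sibling_fe        0.0  -0.000528
         trio        0.1   0.017430
```

The true causal effect is zero, yet the unrelated design rejects the null
in every one of the 20 iterations with a mean bias of ≈ 0.21 — close to
the analytic value `sqrt(b_ux/2) ≈ 0.224`, since an offspring's allele is
correlated 1/2 with each parent's.  The within-family designs reject at
roughly the nominal 5% rate and are centred on zero.

The same machinery works on one cohort at a time:

```python
from sibmr import cohort_assoc_table, make_summary_stats, ivw
from dataclasses import replace

coh = simulate_cohort(replace(cfg, seed=1))
ex = cohort_assoc_table(coh, "family_fe", "x")   # per-SNP γ̂_j
ou = cohort_assoc_table(coh, "family_fe", "y")   # per-SNP Γ̂_j
est = ivw(make_summary_stats(ex, ou))
print(f"IVW beta = {est.beta:.3f} (SE {est.se:.3f}, p = {est.p:.2f})")
```

```
IVW beta = 0.049 (SE 0.040, p = 0.22)
```

A command-line interface mirrors the library
(`sibmr simulate | assoc | score | iv | mr | study | shrinkage`); run
`sibmr --help` for the subcommands and flags.

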