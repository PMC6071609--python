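# halfsibgs

Genomic prediction for open-pollinated half-sib progeny trials — the design
under which most undomesticated forest trees (eucalypts grown for essential
oil among them) enter breeding programs. The package compares four breeding-
value prediction models under replicated sixfold cross-validation at several
LD-pruned SNP densities, and ships a synthetic population generator so the
whole pipeline is testable end-to-end without field data.

**Who it is for:** quantitative geneticists and breeders evaluating whether
marker-based selection beats pedigree selection in shallow-pedigree
populations, and how much trait-architecture weighting of the genomic
relationship matrix helps.

## Models

With phenotypes **y**, postblock fixed effects **b** and additive values
**a**, all models fit the animal model

> y = Xb + Za + e,  a ~ N(0, K·σ²ₐ),  e ~ N(0, I·σ²ₑ)

by REML, differing only in the kernel K:

- **ABLUP** — K = A, the pedigree numerator relationship matrix (tabular
  method; recorded half-sibs 0.25).
- **GBLUP** — K = G = M_c M_cᵀ / Σ 2pᵢ(1−pᵢ), the realized genomic
  relationship from {-1, 0, 1} dosages centered by 2pᵢ−1.
- **BayesB** — marker effects with a point mass at zero (probability π) and
  a scaled-inv-χ²(ν, scale) slab; variational inference by default, Gibbs
  sampling as a cross-check; (ν, κ=1−π) tuned by cross-validated MSE over a
  3 × 3 grid.
- **BLUP|GA** — K = T(ω) = ωS + (1−ω)G, where S up-weights the SNP subset
  M_S (top 0.1% of squared BayesB effects µ², plus flanking SNPs) through a
  mean-one diagonal weight matrix D. ω is scanned over {0, 0.1, …, 1}; ω = 0
  reduces exactly to GBLUP, so BLUP|GA's per-fold ability never falls below
  GBLUP's.

Predictive ability is Pearson r(GEBV, y_adj) on masked validation
individuals, averaged fold→replicate→overall.

## Worked example

```python
from halfsibgs import (PopulationConfig, TraitConfig, simulate_population,
                       simulate_trait, adjust_phenotypes, filter_maf, build_G,
                       make_cv_plan, gblup, predict_gebv, predictive_ability,
                       blupga_predict)

# 40 open-pollinated families x 12 progeny, 5000 SNPs
pop = PopulationConfig(n_families=40, progeny_per_family=12, n_snps=5000, seed=1)
genotypes, pedigree = simulate_population(pop)
genotypes = filter_maf(genotypes, 0.05)

# h2 = 0.5 trait with one QTL carrying 30% of the genetic variance
trait = adjust_phenotypes(simulate_trait(
    genotypes, TraitConfig(heritability=0.5, n_qtl=100,
                           large_effect_variance_fraction=0.3, seed=5)))

G = build_G(genotypes)
plan = make_cv_plan(genotypes.n_individuals, k=6, reps=1, seed=3)
val = plan.validation_indices(rep=0, fold=0)
val_ids = [genotypes.sample_ids[i] for i in val]

fit = gblup(trait, G, validation_ids=val_ids)
gebv = predict_gebv(fit, val_ids)
print(f"estimated h2:        {fit.variance.h2:.3f}")
print(f"GBLUP ability:       {predictive_ability(gebv, trait.y_adj[val]):.3f}")

profile, _ = blupga_predict(genotypes, trait, val_ids, G, seed=4)
print(f"BLUP|GA ability:     {profile.max_ability:.3f} at omega={profile.argmax_omega}")
print(f"profile outcome:     {profile.outcome}")
```

Output:

```
estimated h2:        0.318
GBLUP ability:       0.243
BLUP|GA ability:     0.376 at omega=0.1
profile outcome:     interior
```

Reading it: REML under the genomic kernel attributes about a third of the
phenotypic variance to additive effects in this fold; plain GBLUP predicts
the 80 masked individuals' adjusted phenotypes at r = 0.24; up-weighting the
handful of SNPs that BayesB flags (which include the large-effect QTL)
lifts the validation correlation to 0.38, with the best blend placing 10%
weight on the architecture kernel — the mechanism that makes
architecture-weighted GBLUP pay off exactly when a tagged large-effect
locus exists.

The same experiment end-to-end, for all four models, two trait
architectures and three nested SNP panels:

```bash
halfsibgs compare --n-snps 5000 --reps 10 --out comparison/
```

## Command line

`halfsibgs simulate | qc | kinship | predict | compare` — thin wrappers over
the library that read/write VCF and TSV. See `halfsibgs <cmd> --help`.

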