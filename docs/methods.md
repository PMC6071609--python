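# Methods

## The population the simulator emulates

`halfsibgs` targets genomic prediction in a single-generation open-pollinated
progeny trial: 40 maternal half-sib families of 12 progeny (N = 480), the
design typical of early forest-tree breeding programs. Each family's mother
is a phased founder drawn site-independently from allele frequencies uniform
on the configured MAF range (default [0.05, 0.5]); each progeny receives one
recombinant maternal gamete and one paternal gamete. Open pollination is
modelled as a distinct random sire per progeny, equivalent to a paternal
gamete drawn from the founder allele-frequency pool, which gives maternal
half-sib families with expected additive relationship 1/4. A configurable
fraction of progeny instead receive gametes from a single family-shared
sire (expected relationship 1/2 for such pairs), and a configurable fraction
of individuals have their *recorded* family relabelled while their genetics
stay untouched — the two pedigree-error modes seen in real field pedigrees.

Meiosis uses a uniform genetic map (default 1 Morgan per chromosome, 11
chromosomes) with adjacent-SNP recombination fractions set by SNP spacing,
so within-family co-segregation is present but founders are in linkage
equilibrium. Consequently *population-level* LD is essentially absent: the
nested LD-pruned panels built from simulated data are nearly identical in
size, unlike the 500K→100K→10K reduction seen with real short-range LD.
Passing pruning tests therefore demonstrate the algorithm's correctness
(window logic, nesting, thresholds), not realistic panel attrition. Other
features of real data the generator does not emulate: genotyping error and
missingness, selection on the mothers, spatial autocorrelation beyond the
block factor, and non-additive genetic variance.

Traits are strictly additive: g = Σ centered-dosage × effect over `n_qtl`
QTL (default 100, Gaussian effects), rescaled so Var(g)/Var(g+e) equals the
configured narrow-sense h². An optional designated QTL absorbs a set
fraction of Var(g) ("large-effect" regime). Phenotype = g + postblock shift
(4 blocks, N(0, 0.5) shifts) + Gaussian residual; sqrt/log transformations
are applied after noise, with a recorded positivity shift when needed. The
paper-style regimes used in the comparison runner are oil-like h² = 0.5 and
biomass-like h² = 0.15 — the source study does not print numerical
heritabilities, so these are the package's own representative defaults.

## Relationship matrices

The genomic matrix G uses the centered cross-product on {-1, 0, 1} dosages:
columns centered by 2p−1 (p = counted-allele sample frequency), scaled by
Σ 2p(1−p). This is the construction whose expectations are 0.25/0.50/0/≈1
for half-sibs/full-sibs/unrelated/diagonal. Because p is estimated from the
structured sample itself, realized pair means sit slightly below
expectation (≈0.242 for half-sibs at N = 480, 5000 SNPs; the across-family
mean is ≈ −0.008 ≈ −1/(n−1) by the zero-sum property of sample-centered
cross-products). Monomorphic SNPs contribute nothing to the denominator and
are rejected; the pipeline always MAF-filters first.

The pedigree matrix A is built by the general tabular method over founders
(one dam per recorded family plus any recorded sires, all unrelated and
non-inbred) and progeny, so recorded half-sibs get 0.25 and recorded
full-sibs 0.5, and deeper pedigrees also work.

The weighted matrix S restricts the same construction to a selected subset
M_S, replacing the implicit identity with a diagonal D of SNP weights
normalized to mean one, and summing the denominator over M_S only — both
choices keep S on G's scale. The trait-specific kernel is T(ω) = ωS + (1−ω)G.

## Mixed model

The animal model y = Xb + Za + e with a ~ N(0, Kσ²_a), e ~ N(0, Iσ²_e) is
fitted by REML in the single variance ratio γ = σ²_a/σ²_e. After one
eigendecomposition of the (training-row) kernel, each restricted-likelihood
evaluation is O(n); the profile likelihood is maximized by bounded scalar
search on log γ ∈ [−10, 10] (xatol 1e-8), with σ²_e profiled out and fixed
effects by GLS at the optimum. A 1e-6 diagonal ridge guards against the
rank deficiency of finite-SNP kernels (configurable; set to 0 in oracle
tests). Masked individuals receive breeding values by the kernel extension
â_v = K_vt(K_tt + λI)⁻¹(y_t − X_t b̂), λ = 1/γ, which the tests verify
against the explicit matrix formula. Fits use the raw phenotype with the
postblock design in X; the reported ability metric uses the pre-adjusted
y_adj (within-block centering — exact one-way least squares).

## BayesB

Marker effects follow a spike-and-slab prior: zero with probability
π = 1 − κ, else N(0, σ²_j) with σ²_j ~ scaled-inv-χ²(ν, scale). The default
engine is deterministic coordinate-ascent variational inference with a
Bernoulli–Gaussian per-SNP posterior; the per-SNP slab variance uses the
conjugate update E[1/σ²_j] = (ν+1)/(ν·scale + E[β²_j]), the residual
variance is re-estimated each sweep, and convergence is declared when the
largest per-SNP change in E[β] falls below `tol` × sd(y) (default 1e-4,
max 200 sweeps). A single-site Gibbs sampler (integrated-likelihood
indicator update, conjugate draws for effects, slab variances and residual
variance; default 3000 iterations / 1000 burn-in) provides an independent
engine; the tests require the two to agree on the top-effect SNP and the VB
fit to reduce exactly to ridge regression when κ = 1 and the slab variance
is pinned (large ν). When no scale is given it is derived by moment
matching: κ · Σ2p(1−p) · (1+f) · scale·ν/(ν−2) = mvar · Var(y), with
tuning-grid defaults f = 0.10 and mvar = 0.50. Hyperparameters (ν ∈ {4, 8,
12} × κ ∈ {0.05, 0.01, 0.001}) are tuned by mean validation MSE over the
folds of the first CV replicate and then frozen for all replicates — the
same slightly optimistic reuse as the original workflow; a caller can pass
its own fold assignments to hold out a tuning partition instead.

## BLUP|GA

Per fold: BayesB with strong-shrinkage selection priors (κ = 0.001 i.e.
π = 0.999, ν = 4, scale = 0.01) is fitted on training rows only; the SNPs
with µ² in the top 0.1% (k = ⌈fraction × m⌉, so never zero) form the core;
each core SNP's immediately adjacent panel SNPs on the same chromosome are
added; every member's own µ² becomes its raw weight (a switch lets flanks
inherit the core µ² instead); weights are normalized to mean one. S and
T(ω) are built for ω ∈ {0.0, 0.1, …, 1.0} and each T is run through kernel
BLUP. The fold's reported ability is the profile maximum, which by
construction can never fall below plain GBLUP (ω = 0 is in the grid); this
in-fold maximization is optimistically biased, so the full ω profile is
returned for unbiased ω-selection schemes. Ties in the profile resolve to
the smallest ω. If selection finds no signal (all µ² equal) the profile
collapses to {ω = 0} and is flagged.

## Cross-validation

Randomized k-fold plans (default 6 folds × 10 replicates) assign every
individual to exactly one validation fold per replicate, fold sizes
differing by at most one (n = 468 gives exactly 78/390 splits). Predictive
ability is Pearson r(GEBV, y_adj) per fold; the headline number is the mean
over folds within a replicate, then the mean of replicate means. Fold
assignments are shared across models, so contrasts are paired. Constant
prediction vectors yield a missing (NaN) ability with a warning, excluded
from replicate means rather than imputed as zero.

## Problem sizes and numerical choices

The default comparison scenario is desk-scale: N = 480, 5000 SNPs, panels
from pruning windows {2, 8, 30} applied sequentially per chromosome
(keep-first tie-breaking, r² as squared Pearson correlation of dosages,
threshold 0.05), 10 × 6 CV — about three minutes on one core. The
hundreds-of-thousands-of-SNPs scale of real WGS data is configuration, not
code. Known limitations: single-kernel REML only (no multi-trait or
dominance), no single-step A/G blending, no estimation of π from data, and
the simulator's linkage-equilibrium founders understate the benefit of LD
pruning.
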