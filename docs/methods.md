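# Methods

This note documents the models, generative assumptions, numerical choices
and known limitations of `bcnam`. It is the place to look when deciding
whether a passing test on synthetic data says anything about your real data.

## The population simulator

**Genome and meiosis.** Markers live on a centimorgan linkage map (default:
10 chromosomes × 150 cM, uniform marker grid). Meiosis follows the Haldane
model: crossover counts per chromosome are Poisson with mean length/100
Morgans, positions uniform, no interference, starting chromatid a fair coin.
This is the standard neutral recombination model; crossover interference,
recombination hot/cold spots and structural variation are not modeled.

**BC₁-NAM construction.** Each family is F₁ = recurrent × donor, one
backcross to the recurrent parent, then `selfing_generations` rounds of
selfing (default 3, i.e. BC₁F₄ — the number of seed-increase generations is
not uniquely determined by the material's name, so it is configurable).
Parental origin of every allele is tracked explicitly, so identity-by-descent
with the recurrent parent is exact. Unselected BC₁ lines carry 75% of the
recurrent genome in expectation; heterozygosity halves with each selfing
generation (≈ 1/16 of markers at BC₁F₄).

**Selection at major loci.** Breeding programs discard lines carrying the
exotic allele at dwarfing/maturity loci. This is modeled as rejection
sampling of *finished* lines — a line must be homozygous for the
recurrent-parent allele at every designated locus — rather than
per-generation truncation, matching screening applied to finished material.
Selection at four unlinked loci raises mean recurrent-genome share to
roughly 78–80% through linkage drag around the selected loci.

**Family bottleneck (`n_bc1_plants`).** By default every simulated line
descends from its own BC₁F₁ individual (the idealized infinite-family
expectation, used for the Mendelian-expectation checks). Real families are
advanced from one or a few backcross plants, so sibs share the particular
donor segments those plants carried. The packaged benchmark uses
`n_bc1_plants = 2`. This matters scientifically: the family bottleneck is
what makes one or two phenotyped lines informative about their whole family,
and hence what produces the early plateau of the cross-validation ladder.

**Founders.** The recurrent parent is the all-reference haplotype; each
donor flips a seeded fraction of markers (`divergence`, default 0.12 in the
benchmark). A `private_fraction` (benchmark: 0.8) of each donor's flips is
drawn from a donor-exclusive partition of the marker space, modeling exotic
accessions of distinct geographic origin whose novel alleles are largely
family-private — the regime in which training-set family representation has
value. With fully shared donor deviations, family representation is nearly
worthless and the CV ladder flattens; real germplasm sits in between.

**Traits.** Plot values are
`env mean + u_A + u_D + u_AE + u_DE + block + range + row + residual`.
Main additive values are drawn either from the additive kernel
(`u_A ~ N(0, K_A σ²_A)`, the infinitesimal model) or, when `n_qtl` is set,
from sparse normal effects at that many polymorphic markers (oligogenic
architecture; in a BC₁-NAM population polymorphic markers are dominated by
donor introgressions, so sparse effects are largely family-private).
`family_var_share` splits additive variance between a family-level
(donor-determined) effect and within-family segregation; the benchmark uses
0.7 for the high-heritability trait (maturity/height-like: major genes
screened during line development leave families internally uniform) and 0.2
for the low-heritability trait (yield-like). Interaction deviations are
drawn independently per environment from the same kernels — exactly the
block-diagonal covariance that the environment-masked Hadamard kernels
specify. Design effects are i.i.d. normal with user-set variances
(benchmark: 0.05/0.02/0.02 for block/range/row); no spatial correlation is
modeled.

Benchmark variance components (hybrid-mean scale):

| trait | σ²_A | σ²_D | σ²_AE | σ²_DE | σ²_e | n_qtl | family share |
|---|---|---|---|---|---|---|---|
| `trait_high_h2` | 1.0 | 0.1 | 0.2 | 0.05 | 0.4 | 60 | 0.7 |
| `trait_low_h2`  | 0.3 | 0.15 | 0.4 | 0.1 | 1.5 | 60 | 0.2 |

These give plot-level repeatabilities of roughly 0.8 and 0.35 — the spread
observed between maturity/height and grain yield in multi-environment
sorghum hybrid trials.

## Marker QC and diversity

Numeric coding: per marker, the more frequent allele among non-missing calls
is "major" (ties to the lexicographically smaller allele); homozygous major
→ 1, heterozygote → 0, homozygous minor → −1. Filters apply in order —
called in < 25% of parental lines; more than 50% missing (strictly);
indel; MAF < 0.05; heterozygosity > 50% — and each dropped marker is
attributed to the first rule it fails. MAF and heterozygosity are computed
after simple imputation (missing → major homozygote), matching a pipeline
that imputes between the two screens; the bundled imputation is deliberately
naive and adequate only for near-inbred material. Heterozygosity per marker
is the fraction of calls coded 0.

Nei's (1972) standard distance is computed from per-line allele frequencies
{0, ½, 1} implied by the codes; infinite distances (disjoint profiles) are
capped at ln(10⁶) so ordination stays finite. "PCA of the genetic distance"
is realized as classical metric scaling (PCoA): double-center −½D²,
eigendecompose, scale eigenvectors by √eigenvalue; negative eigenvalues are
excluded from variance shares. (Whether the original figures derive from
PCoA of the distance or PCA of the genotypes is ambiguous; PCoA is the
default and the genotype-PCA route is a one-liner with scikit-learn.)

## Trial statistics

Per environment, `Y = μ + Gen + Blk + Ra + Ro + ε`. Variance components come
from EM-REML with every factor random; genotype BLUEs from a second solve
with genotype fixed (sum-to-zero coding, so the intercept is the environment
mean) at those same variance components. EM-REML was chosen over
Newton-type algorithms because its updates are non-negative by construction;
the cost is linear convergence — null components decay toward zero slowly,
so convergence is declared when the largest variance change per iteration
falls below 1e−6 of the phenotypic variance (cap 500 iterations, flag
returned). Estimates at the cap are accurate for the non-null components;
raise `max_iter` when precise null-component shrinkage matters.

Repeatability uses the plot-basis formula `R = σ²g/(σ²g + σ²e/r)` with `r`
the mean plots per entry; in unreplicated layouts without repeated checks,
genotypic and residual variance are confounded and `R` is reported as NaN
with a flag. CVe is `100·√MSE/x̄` — the root-MSE convention, which is
unitless and on the familiar percent scale (an MSE/mean ratio would carry
the trait's units).

The multi-environment GCA model fits
`Y = μ + Blk(Env) + Ra(Env) + Ro(Env) + Env + Mal + Fem + Mal·Fem + Mal·Env
+ Fem·Env + Mal·Fem·Env + ε` with pollinator (male) effects fixed and all
else random. Treatment coding with the check male as reference makes each
coefficient the GLS contrast male − check; Student's *t* at α = 0.05 on the
residual degrees of freedom flags superior males. No multiplicity
correction is applied beyond the per-comparison α, by design.

## The Bayesian GBLUP

Model: `y = Z_E β + u_A + u_D + u_AE + u_DE + ε` on per-environment hybrid
values. Environment means are full-rank fixed effects with a flat prior
(they absorb the grand mean, which would otherwise be confounded). Each
random vector has covariance σ²·K over observations, with K the main-effect
expansion `Z K_hyb Z'` or its environment-masked Hadamard product.

Sampling: each kernel is eigendecomposed once (`K = U S U'`, eigenvalues
below 1e−10 of the largest dropped — the prior in those directions is a
point mass at zero, so truncation is exact, and rank-deficient kernels from
duplicated hybrids are handled for free). In the eigenbasis the full
conditional of the coefficient vector is diagonal, so one update costs two
matrix–vector products per kernel. Variances get scaled-inverse-χ² updates
with prior df 5 and scale set so each prior mean is an equal share of the
sample variance of `y` — a weakly informative convention that keeps the
sampler proper without dominating desk-scale data. Defaults: 10 000
iterations, 1 000 burn-in, thin 2 (4 500 retained draws); identical seeds
give identical chains. Posterior summaries use running means for effects
(memory O(n)) and retain thinned draws for the variances.

Prediction for held-out observations is
`β̄_env + Σ_k K_k(target, train) K_k(train, train)⁺ ū_k`: hybrids absent
from training borrow information purely through kernel covariance. For a
training observation this reduces exactly to its fitted value. Missing
responses are excluded rows (no data augmentation), matching a CV design
where whole lines are held out. With variance components pinned, the Gibbs
posterior means agree with closed-form GLS/BLUP to well under 2% of the
response SD (the key correctness test in the suite).

Known identifiability limit: with few environments the dominance and
dominance-×-environment kernels overlap strongly with each other and with
the residual, so σ²_D/σ²_DE/σ²_e are individually noisy (their sum is well
determined). The acceptance check therefore targets the additive and
residual components.

## Cross-validation ladder

CV*k* training sets = all hybrids of the core families + all check hybrids +
all hybrids of *k* seeded-random lines from every other family; validation =
all hybrids of the remaining lines. Splits are at the line level (all
hybrids of a line move together), checks are never validated, and families
with ≤ *k* lines contribute all lines to training. Accuracy is the Pearson
correlation between predicted and observed per-environment BLUEs, pooled
within trait across validation observations (a per-family breakdown is
available for diagnosis; accuracy is not divided by √h, so values are
comparable to published raw prediction-accuracy ranges). Schemes are
compared by Tukey's HSD (Tukey–Kramer under unequal repeat counts, via
statsmodels), flagging schemes statistically indistinguishable from the
highest-mean scheme.

On the packaged benchmark the ladder reproduces the qualitative published
pattern: accuracy rises when two lines per family enter training, the
high-heritability trait gains more from the first two lines than from five
more, and accuracy is non-decreasing in *k* within sampling error. Problem
sizes were chosen for a single desk CPU: the benchmark uses 10 families × 12
lines × 1 500 markers × 3 environments, CV experiments use 2 000-iteration
chains and 10–20 repeats, and the worked example in the README was produced
by exactly the code shown there.

## What the synthetic data do not show

The simulator emulates structure, not biology: no genotyping error or
missingness mechanism (QC filters are exercised by constructed fixtures,
not by realistic error processes), no spatial field trend beyond i.i.d.
block/range/row effects, no epistasis, no trait correlations, no
photoperiod-by-environment physiology behind G×E (interactions are draws
from the prescribed covariance), and donor divergence is synthetic rather
than an empirical allele-frequency spectrum. Passing tests demonstrate that
the estimators recover what the generative model puts in at these scales —
not that real sorghum trials satisfy the generative assumptions.
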