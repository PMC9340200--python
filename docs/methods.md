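# Methods

`stratlab` studies how the choice of principal-component (PC) correction —
cohort-specific versus projection onto external reference panels, applied in
GWAS discovery and/or polygenic-score validation — affects polygenic risk
score (PRS) performance and residual population-structure confounding. All
analyses run on synthetic cohorts whose structure, confounding, and sample
roles emulate a two-biobank design: a large discovery cohort, a held-out
target set from the same population, a second genetically close target
cohort, and external reference panels of varying relatedness.

## Cohort simulator

### Genotypes

Genotypes follow the Balding–Nichols F-model. For each variant an ancestral
frequency `p` is drawn uniformly from [0.05, 0.95]; population `k`'s
frequency is a Beta draw with mean `p` and variance `F_k·p(1−p)`, and
genotypes are two binomial draws from that frequency. `F_k = 0` collapses
the Beta to a point mass (the population keeps `p` exactly). Under a
star-shaped history the pairwise differentiation of populations `i` and `j`
is approximately `(F_i + F_j)/2`, which is how a user-supplied pairwise
matrix is converted to per-population divergences (least squares, exact when
the matrix was built from a star).

An optional admixture-cline mode interpolates each population's base
frequency between two diverged ancestral pools (`(1−a_k)·p_A + a_k·p_B`,
pools separated by `cline_fst`) before applying the population's own drift.
This gives all populations a shared axis of differentiation plus
population-specific drift — the minimal geometry in which an external
reference panel can *partially* span another cohort's internal structure.
The strength with which a panel's cline-derived PC proxies membership in the
two discovery subpopulations scales as `(Δa)²·m·F_AB` (m = variants used),
so the emulation preset places the two discovery subpopulations close on the
cline (Δa = 0.03) while giving them clearly distinct drift.

Variants are placed uniformly (without duplicate positions) on two synthetic
120-Mb chromosomes so that kilobase windows for pruning and clumping are
meaningful. Variants are mutually independent by default; an optional
block-LD mode draws haplotypes from a Gaussian copula with AR(1) latent
correlation ρ inside blocks, used by the tests so pruning and clumping do
nontrivial work. Missing calls can be injected at a configurable rate
(default 0). Allele pairs are drawn from the non-palindromic set; QC
fixtures inject palindromic/indel/duplicate records explicitly.

### Emulation preset

Five populations:

| label      | admixture a | own drift F | role                                   |
|------------|------------|-------------|----------------------------------------|
| brit_a     | 0.00       | 0.002       | discovery + same-cohort target + panel |
| brit_b     | 0.03       | 0.006       | discovery + same-cohort target + panel |
| est        | 0.10       | 0.002       | other-cohort target + its panel        |
| eur_other  | 0.30       | 0.004       | European reference panel               |
| non_eur    | 1.00       | 0.020       | non-European reference panel           |

with `cline_fst = 0.15`. Resulting pairwise differentiation: ≈ 0.003–0.004
between the discovery subpopulations and between the two target cohorts,
≈ 0.01 to the other-European population, ≈ 0.09 to the non-European
population — the relationships a UK-style cohort, an Estonian-style cohort,
and a worldwide reference panel would show. The European panel deliberately
does **not** sample the discovery subpopulations: like a continental
reference, it sees their shared cline but not their internal drift, which is
what makes projection-based correction partial rather than complete. The
all-populations panel is the union of the European and non-European panels.

Role sizes scale the original design's counts (targets ≈ 7,100; panels
5,000 / 2,504 / 503 / 2,001) by a configurable factor (default 0.5); the
discovery size is set separately (default 8,000) because the original
discovery set (~350k) is far beyond desk scale.

### Traits

A trait is built on a unit-variance scale from: a polygenic component over
`n_causal` variants with i.i.d. normal per-allele effects, rescaled to an
exact variance share equal to `heritability`; an ancestry component — the
sample's population-level geography score, standardized and scaled to share
`structure_effect`; fixed covariate effects (age ≈ 0.01/yr, sex 0.5, batch
0.1, all in trait SD units); and Gaussian noise absorbing the remainder.
The raw polygenic score is centered within populations before rescaling:
causal allele-frequency drift would otherwise hand the trait a random
between-population mean shift (a χ²-distributed draw over seeds), and the
generator's contract is that `structure_effect` alone sets the
trait–ancestry correlation. Allele frequencies are untouched, so estimated
scores (PRSs) still carry drift-driven ancestry correlation — only the
*true* trait is free of it.
Trait geography follows the populations' order along the cline but is not
proportional to admixture, so the discovery subpopulations differ more in
trait than their admixture gap alone would imply — emulating a phenotype
cline steeper than genome-wide ancestry.

Defaults for the two study traits: the structured ("height-like") trait has
h² = 0.4 and structure share 0.08 globally, which realizes ≈ 1–2% of
variance within a single cohort — the order of magnitude the original
study's trait–PC regressions show for height (the global share dilutes
within a cohort because the cross-continental score range dominates the
global standardization). The non-structured ("BMI-like") trait has h² = 0.3
and structure share 0.005, realizing a within-cohort trait–PC association
below the multiple-testing threshold, mirroring a trait whose PC
correlation is borderline non-significant while its PRS still carries
detectable structure.

The architecture is deliberately highly polygenic relative to desk-scale
GWAS power (`n_causal = 1,000` of 10,000 variants at discovery n = 6,000 in
the standard run): individual causal variants are rarely genome-wide
significant, the best-performing p-value threshold is therefore permissive,
and the score aggregates thousands of weakly measured effects. That is the
regime in which uncorrected structure accumulates across variants into the
PRS — the phenomenon under study. With few strong causals the threshold
search retains only top hits and every GWAS version yields an almost
identical, structure-free score; the contrasts of interest vanish. These
values are simulation-design choices, not claims about height or BMI
genetics.

## Pipeline stages

**Variant QC** removes, in order: duplicate chrom:pos records (first kept),
indels (any allele ≠ 1 nucleotide), palindromic A/T and C/G SNPs
(strand-naive), variants with > 5% missingness, and minor allele frequency
< 0.01 (complete-case frequencies). Each variant is counted at the first
filter that removes it, making the QC report deterministic; the operation is
idempotent.

**LD pruning** is sliding-window greedy (window 50 variants, step 10,
r² > 0.1 dropped) per chromosome on mean-imputed standardized dosages;
within an offending pair the later-positioned variant is dropped
(deterministic tie-break). Monomorphic variants are removed up front.

**PC spaces** are built per reference panel: LD pruning on the panel,
per-variant standardization (missing → 0 after centering), eigendecomposition
of the standardized genotype covariance, then up to five rounds of outlier
removal (> 6 SD along any of the top 10 PCs) with early stop; standardization
constants come from the final post-removal panel. Large panels with few
requested components use a randomized truncated SVD (fixed random state;
exact SVD otherwise), and eigenvector signs are fixed by orienting each
loading's largest-magnitude entry positive, so results are reproducible
across runs and linear-algebra backends. Projection multiplies
panel-standardized cohort dosages by the orthonormal loadings — the
least-squares solution for the coordinates; the projected cohort's own
allele frequencies are never used. Swapped alleles flip the dosage;
inconsistent alleles are an error. Shrinkage-corrected projection is a
config stub that raises if requested (sensitivity analyses elsewhere found
it does not change the comparisons this package makes).

**GWAS** fits, per variant, OLS of the trait on
[1, age, sex, batch, dosage, PC1..PC20] (the PC block omitted for the
control version). For complete dosages the loop is computed as one
residualization-then-batched-regression pass (trait and all dosages
projected off the shared covariates once), algebraically identical to
per-variant OLS; variants with missing calls fall back to the per-variant
complete-case fit, which also serves as the reference path. P-values use
the t distribution with residual degrees of freedom. Genomic inflation λ is
the median 1-df chi-square quantile of the p-values divided by 0.4549364.

**PRS construction** clumps summary statistics greedily in ascending
p-value order (r² > 0.05 within ±1,000 kb claimed by the index variant;
ties broken by chrom, position), using the target cohort's genotypes as the
LD reference — the behavior of the standard scoring tool, which clumps
within the target data. Scores are effect-allele dosage sums weighted by
beta; missing dosages contribute the variant's mean. Eight p-value
cut-offs (5e-5 … 0.5) are searched; the threshold maximizing the validation
model's total R² (covariates included; a PRS-only objective is available by
option) wins, ties to the smaller threshold; the winning score is
standardized to mean 0, SD 1 in the target set.

**Validation** fits trait ~ [1, PRS, age, sex, batch(, PC1..PC20)] for the
5 × 5 grid of PRS versions × PC-adjustment choices. BIC = −2·loglik +
k·ln n with the Gaussian likelihood at the MLE and k counting every
coefficient plus the residual variance (any consistent k convention leaves
ΔBIC orderings unchanged, which is all that is interpreted). ΔBIC is taken
against the grid minimum and binned <6 weak / 6–10 strong / >10 very
strong, boundaries assigned to "strong". Added R² is total R² minus the
matched no-PRS model's R².

**Decomposition** residualizes the trait on age, sex, and batch, then fits
six models — trait_res ~ PCs; PRS ~ PCs; trait_res ~ PRS; trait_res ~ PCs +
PRS; trait_res_PRS ~ PCs; trait_res_PCs ~ PRS — each tested against the
intercept-only model by the upper-tail overall F-test. Significance uses a
Bonferroni cut-off recomputed from the actual family size (0.05/10 = 0.005
for the default 5 PRS × 2 traits). PCs here are the cohort-specific set;
projected-PC variants are available by option.

## Problem sizes

The standard experiment (`ExperimentConfig` defaults) uses discovery
n = 8,000, targets ≈ 3,550 each, panels 2,500 / 1,252 / 251 / 1,000, and
20,000 variants. The acceptance script and acceptance tests run the same
design at discovery n = 6,000 with 10,000 variants, which preserves every
qualitative contrast while keeping a full run to a few minutes; calibration
fixtures use n = 2,000 × m = 5,000, and determinism checks a miniature
configuration. These sizes are the package's chosen study conditions, and
the absolute R²/ΔBIC magnitudes they produce are *not* the original
biobank-scale values — only the orderings and significance patterns are
comparable.

## What the simulation does and does not show

Passing tests demonstrate the mechanism — external-projection PC correction
is partial, residual structure accumulates in the PRS, cohort-specific
correction yields the best-fitting validation models, and a non-structured
trait's PRS still carries significant structure — under an idealized model:
unrelated individuals, unlinked variants (no realistic LD maps), two
discrete confounding axes rather than continuous fine structure, fully
genotyped causals, and Gaussian traits. Effect sizes on real biobank data,
the influence of relatedness, imputation, assortment, or participation
bias, and fine-scale haplotype structure are outside what this package can
establish. At desk scale the ranking among *partially* corrected score
versions (e.g., all-reference vs European-only panels) and among the
BMI-like trait's five score versions is close to the resolution limit;
single-seed reversals there are expected and honest.

## Numerical choices

- Mean imputation (0 after centering) for missing dosages in PCA,
  projection, pruning r², and scoring; complete-case fits in GWAS.
- QR-based projections for shared-covariate residualization; per-variant
  inverse only on the missing-data path.
- Batch enters as dummy variables, reference level lexicographically first.
- Clumping precomputes the banded r² adjacency with blocked matrix products
  (band = the ±window); the greedy pass then runs on that sparse graph.
  Results are identical to the direct per-index implementation.
- p = 0 is clamped to the smallest positive float before the chi-square
  quantile transform (with a warning).
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed reproduces every
  output byte-for-byte.
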