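# Methods

`firmqtl` implements the forward-genetics triangulation used to dissect a
single large-effect, incompletely dominant locus for fruit firmness in
cultivated strawberry (*Fragaria × ananassa*): a seeded population
simulator, REML variance components and heritability on a clone-mean
basis, a kinship-adjusted single-marker association scan, a
quantitative-trait-transcript (QTT) correlation scan with polygenic
adjustment, a matrix-formulated eQTL scan, and marker-effect /
validation statistics. This note records the models, the defaults and
why, the numerical choices, and the limitations.

## Population simulator (`simpop`)

Genotypes are biallelic dosages 0/1/2 of the *favorable*
(firmness-increasing) allele, drawn at Hardy–Weinberg proportions with
per-marker allele frequencies uniform over `maf_range` (default
0.05–0.5). The major locus is pinned at frequency 0.5 so that all three
genotype classes are well represented, as in a breeding collection
segregating for the locus. All markers sit on one synthetic chromosome
("chr6A") at evenly spaced positions; no linkage disequilibrium is
simulated beyond the single causal column.

The genotypic value of individual *i* is

    g_i = a·(x_i − 1) + d·[x_i = 1] + polygenic_i

with defaults a = 0.10 kg-force and d = 0.04 kg-force (degree of
dominance |d/a| = 0.4, incomplete dominance of the favorable allele).
The polygenic background is realized through the non-causal markers
with i.i.d. Gaussian effects and rescaled *post hoc* so the realized
total genotypic variance among clones equals `sigma2_G` exactly
(default 0.010 kg-force², making the major locus account for half the
genetic variance). The exact rescaling removes Monte-Carlo drift from
heritability-recovery tests. When `sigma2_G = 0` the major locus is the
only genetic term. Background dominance is omitted: the major locus is
the only non-additive term, consistent with a genetic architecture that
is predominantly additive.

Phenotype observations follow a multi-environment clone-replicated
design,

    y = grand_mean + L_l + g_i + Y_y + LY_ly + GY_iy + LYB_lyb + e,

with fixed location effects and independent Gaussian random effects.
Defaults: 2 locations × 2 years × 2 blocks × 3 harvests = 24
observations per individual, `sigma2_GY = 0.010`, `sigma2_e = 0.12`,
so the clone-mean phenotypic variance is
0.010 + 0.010/2 + 0.12/24 = 0.020 and the broad-sense clone-mean
heritability is exactly H² = 0.5. Firmness residuals are Gaussian (the
measurement distribution is not otherwise constrained). The nuisance
variances (`sigma2_Y`, `sigma2_LY`, `sigma2_LYB`) are small positive
values; they do not enter clone-mean heritability.

Transcript counts are negative binomial with mean CPM × libsize / 10⁶
and variance μ + φμ² (default dispersion φ = 0.1, typical of bulk
RNA-seq after biological replication). One RNA sample per individual
(fruit are pooled within clone). Library sizes are log-uniform over
5×10⁵–2×10⁶. The focal softening-gene transcript follows
`cpm_by_genotype = (2000, 1000, 160)` across favorable-allele dosage
0/1/2 — a 12.5-fold contrast between wildtype and mutant homozygotes —
while every other gene has a genotype-independent baseline CPM drawn
log-uniformly over 1–1000. The focal gene's midpoint is placed 1 kb
from the major locus so any sensible cis window contains it.

Scale: defaults use 200 individuals, 500 markers and 2000 genes. The
marker and transcript panels are deliberately scaled down from the
array/transcriptome scale (~49 k SNPs, ~60 k transcripts) so a full
pipeline run takes seconds; see Limitations for a consequence of the
smaller marker panel.

Full-sib families are simulated by Mendelian single-locus transmission;
a het × het cross segregates 1 : 2 : 1.

All draws flow from `numpy.random.default_rng([seed, stream])` with a
fixed stream per operation, so outputs are bit-reproducible for a given
`SimConfig` regardless of call order.

## REML and heritability (`linmix`)

Variance components of Gaussian mixed models with crossed independent
random factors are estimated by direct maximization of the restricted
log-likelihood over the variance ratios γ_k = σ²_k/σ²_e, with σ²_e
profiled out. The likelihood is evaluated through the Woodbury
identity on the q×q random-level cross-product matrix (q = total
random levels, a few hundred here), so no n×n factorization is formed.
The gradient is analytic (score equations per component); optimization
is bounded L-BFGS-B on log γ with a restart from the best iterate on a
line-search stall and a short Nelder–Mead fallback. Boundary estimates
(γ → 0) are returned as zero. Two canonical model specifications are
provided: a variance-component fit with genotype random (for σ²_G,
σ²_G×Y, σ²_e) and an EMM fit with genotype fixed (for per-individual
means), mirroring the standard two-pass analysis of multi-environment
clonal trials.

Estimated marginal means average model-predicted cell values (random
effects at zero) with equal weight over the combinations of
non-genotype fixed factors each individual was observed in; cells
empty for an individual are dropped from its average. Interaction
terms are encoded by concatenated level labels; the fixed design is
pruned to full column rank by pivoted QR, which leaves fitted values
(and hence EMMs over observed cells) invariant.

Heritabilities on a clone-mean basis:

    H² = σ²_G / (σ²_G + σ²_G×Y / y + σ²_e / (r·y))
    h² = σ²_A / σ²_P̄

with y years and r the harmonic mean number of replications per
genotype within a year. σ²_A comes from a kinship-based REML fit of
the individual means (y = μ + g + e, g ~ N(0, σ²_A K)), equivalent to
RR-BLUP when K is the VanRaden realized relationship matrix. Both
ratios are clamped to [0, 1] with the clamping logged.

## Kinship and association scan (`assoc`)

K = ZZᵀ / (2 Σ p_j(1−p_j)) with Z the column-centered dosage matrix;
missing dosages are mean-imputed per marker (the standard behavior of
mixed-model GWAS tools). The null model y = Xβ + g + e with
g ~ N(0, σ²_g K) is fitted by the spectral (EMMA-style) method: K is
eigendecomposed once and the restricted likelihood is profiled over
δ = σ²_e/σ²_g on a 101-point log₁₀ grid spanning [10⁻⁵, 10⁵], then
polished by bounded Brent search in the best bracket. The scan holds δ
at the null estimate, adds each marker to the rotated GLS regression
via projection (Frisch–Waugh under GLS), re-estimates the residual
scale per marker, and reports a Wald t test with n − p − 1 degrees of
freedom. With K = I this reduces *exactly* to the OLS t test, which is
the oracle used in the tests. Monomorphic markers are reported with
p = 1 and a flag rather than dropped.

The genome-wide threshold is Bonferroni, −log₁₀(α/m); with m = 49 330
and α = 0.10 this is 5.69 (≈ 5.7). α defaults to 0.05 and is
configurable.

Per-marker variance explained: σ²_M is taken as the variance across
individuals of the fitted genotype-class means (each individual
assigned its dosage-class mean). This is an approximation to a
bias-adjusted REML semi-variance, which is not fully specified in the
source analyses; it is unbiased up from a small (k−1)/n inflation.
PVE = σ²_M/σ²_P̄ and GVE = σ²_M/σ²_G, clamped to [0, 1] with a warning.

## Transcript normalization and QTT (`qtt`)

TMM scaling factors re-implement the trimmed-mean-of-M-values
procedure: reference column = sample whose upper-quartile count
proportion is closest to the mean; genes zero in either sample
excluded; 30% two-sided trim on log-ratios and 5% on average absolute
intensity (ranks with midranks for ties); surviving log-ratios averaged
with inverse asymptotic-variance weights; factors normalized to
geometric mean 1. The test suite checks the factors against both an
independent brute-force implementation and edgeR's `calcNormFactors`.

Expression filtering keeps a gene iff CPM ≥ `min_cpm` (default 1) in at
least `min_samples` samples (default 10% of samples); this is a
deliberate simplification of design-aware filtering heuristics, which
depend on group sizes that are not defined for a correlation scan.

log2 CPM uses a library-size-scaled prior count:
log₂((count + p·s_j) / (L_j + 2 p·s_j) × 10⁶) with L_j the effective
(TMM-scaled) library size and s_j = L_j / mean(L). Note CPM is by
definition not invariant to rescaling all library sizes; a common
factor shifts every value by the same constant, which leaves all
between-sample contrasts and correlations unchanged.

The phenotype is adjusted for polygenic background by taking the
environmental residuals of the kinship model, ê = y − μ̂ − BLUP(g)
(GRAMMAR-style residuals); transcripts are not adjusted. Each gene's
log2 CPM profile is then correlated with ê (Pearson r; two-sided p from
the t transform with n−2 df; default significance threshold raw
p ≤ 0.005). Zero-variance genes are flagged and excluded from
significance. Significant genes are grouped into co-expression modules
by average-linkage hierarchical clustering on 1 − r distance, cut to
`n_modules` (default 3).

## eQTL scan (`eqtl`)

Every (marker, gene) pair is a simple linear regression of expression
on additive dosage, evaluated through the correlation identity
t = r√(n−2)/√(1−r²) as one product of standardized matrices — exactly
equal to per-pair OLS, as the tests verify. Pairs are labelled cis when
marker and gene midpoint are within a window (default 1 Mb,
configurable; the appropriate window is genome- and LD-dependent) on
the same chromosome. The top cis record for a gene is the minimal-p cis
pair, ties broken by smaller distance then lower position.

## Marker evaluation (`markereval`)

Genotype classes are keyed by favorable-allele dosage. The additive
effect is â = (ȳ₊/₊ − ȳ₋/₋)/2 (positive for the favorable allele) and
the dominance deviation d̂ = ȳ₊/₋ − (ȳ₊/₊ + ȳ₋/₋)/2; contrast tests
use pooled within-class variance with a Welch–Satterthwaite fallback
when class variances differ more than 4-fold. Degree of dominance is
|d̂/â| (undefined at â = 0, flagged). Segregation against an expected
ratio (default 1:2:1) is a Pearson χ² with df = classes − 1.
Concordance between call sets reports call rate = called/total in the
test set and accuracy = concordant/both-called; reference-missing
samples drop out of the accuracy denominator only. Fold changes are
reported rounded half-away-from-zero to one decimal.

## Pipeline and configuration (`pipeline`, `cli`)

Stages (`simulate`, `heritability`, `gwas`, `qtt`, `eqtl`,
`marker-eval`) communicate only through declared files (VCF v4.2 for
genotypes, metadata-bearing TSVs otherwise), so deleting intermediates
and rerunning with the same seed reproduces them bit-identically. A
JSON manifest records stage status, outputs, seed, version and wall
time. The CLI exposes one subcommand per stage plus `run-all`; exit
codes are 0 (ok), 2 (configuration error), 3 (stage failure).
Configuration is a flat YAML mapping; simulator fields may be set at
top level.

## Numerical choices

- REML optimizer tolerances: L-BFGS-B ftol 10⁻¹⁴ / gtol 10⁻¹⁰; variance
  ratios bounded in [e⁻¹³·⁸, e¹³·⁸]; components below 10⁻¹⁰·σ̂²_e
  snapped to zero.
- Kinship eigenvalues are clipped at zero (PSD up to round-off) before
  spectral profiling.
- Correlations are clipped to [−1, 1] before the t transform; 1 − r² is
  floored at 10⁻³⁰⁰ to keep perfect correlations finite.
- Tie-breaks: top cis-eQTL ties resolved by distance then position with
  a stable sort; TMM trims use midranks; hierarchical modules use
  SciPy's average-linkage merge order.
- Degenerate inputs: constant response → all variance components zero;
  constant genes/markers are flagged or skipped, never silently
  dropped from tables that promise one row per unit.

## What the simulations do and do not show

The generator reproduces the statistical skeleton of the study — a
major incompletely dominant locus on a polygenic background with
clone-mean H² ≈ 0.5, replicated multi-environment phenotypes, a
silenced focal transcript, 1:2:1 families — so passing recovery tests
show the estimators are correct under the assumed model. Real data
differ in ways the generator does not emulate: linkage disequilibrium
(here the causal marker is a single independent column; in reality a
haplotype of tagging SNPs hits together), population structure and
family stratification beyond what VanRaden K captures, non-Gaussian
residuals, shared-environment expression covariance among genes, and
missing genotype calls at realistic rates.

Two quantitative consequences are worth stating. First, with a
desk-scale marker panel the causal locus is a non-negligible fraction
of the kinship matrix, so the polygenic adjustment (environmental
residuals) absorbs part of the major-locus signal and attenuates the
focal QTT correlation relative to an array-scale panel (measured
r ≈ −0.34 at 500 markers vs ≈ −0.42 at 49 330); this is the familiar
deflation of GRAMMAR-type residuals at causal loci. Second, at the
full array scale an LD-free simulation makes "causal marker is the
single top hit" harder than in real data, where several linked SNPs
tag the locus. The defaults therefore keep the scaled-down panel and
report both behaviors in the test suite.

## Known limitations

- No LD, no octoploid subgenome structure, no sequence-level
  simulation.
- The EMM machinery supports factorial designs with interactions but
  not covariates (continuous fixed effects) or heterogeneous residual
  variances.
- The kinship-based h² estimator is noisy at n = 85 (single-dataset
  estimates range roughly 0–0.9 under the default conditions); the
  acceptance script therefore averages it over replicate simulated
  collections.
- PVE/GVE use the fitted-class-means variance, a slight (k−1)/n-inflated
  approximation, flagged in output.
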