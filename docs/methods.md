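# Methods

## Pipeline overview

`pleioscan` implements a five-stage analysis of two GWAS summary-statistic
sets: (1) quality control and allele harmonization against a reference
panel; (2) LD-score regression for SNP heritability and cross-trait genetic
correlation; (3) eQTL-weighted gene–tissue association with genomic
control; (4) harmonic-mean combination of per-tissue P-values; (5)
conditional and conjunction conditional FDR for pleiotropy, followed by
descriptive characterization (effect-size correlations, genetic risk
scores). A synthetic-data generator supplies all inputs with ground truth.

## Quality control and harmonization

Five rules are applied in a fixed order, each SNP attributed to the first
rule that removes it so the report's counts always sum to the input size:
non-biallelic records (including indels) and strand-ambiguous A/T, C/G
pairs; duplicated ids (all copies removed — the conservative reading) and
ids not matching `rs` + digits; SNPs inside excluded high-LD regions
(defaults: the MHC, chr6:28.5–33.3 Mb, and chr8:7.2–12.5 Mb; intervals
closed on both bounds, positions 1-based); SNPs absent from the panel; and
allele-set mismatches against the panel (order-insensitive). Harmonization
then orients every effect to the panel's alternate allele, flipping Z signs
where the effect allele is the panel reference. Harmonization is an
involution: re-expressing records in the opposite orientation and
re-harmonizing reproduces the same Z vector.

## LD-score regression

LD scores use the small-sample-adjusted estimator
r̂²ₐ = r² − (1 − r²)/(n − 2), summed over retained SNPs within half a
10 Mb window on the same chromosome (self term included), so independent
pairs contribute zero in expectation. SNP retention requires empirical
MAF > 0.01 and a Hardy–Weinberg χ²(1) goodness-of-fit P > 1e-5.

Both regressions are weighted least squares with weights 1/max(ℓ, 1), a
standard heteroskedasticity proxy, and free intercepts (the cross-trait
intercept absorbs sample overlap). Standard errors come from a
delete-one-block jackknife with 200 contiguous blocks by default; the
genetic correlation is jackknifed as the full ratio gencov/√(h₁²h₂²), the
three regressions sharing blocks. Two refinements of production LDSC
software are deliberately omitted — two-step intercept estimation and the
max-χ² filter — because acceptance here is parameter recovery on synthetic
data, not replication of a particular real-data estimate. If either h²
estimate is non-positive the correlation is undefined; the result is
flagged and the P-value suppressed. At desk scale (5,000 SNPs) a jackknife
block (25 SNPs) can be smaller than an LD block (40 SNPs), which slightly
understates standard errors; block counts are configurable.

## Gene–tissue association and genomic control

The statistic (z·w)²/(wᵀRw) divides the squared weighted Z-sum by its null
variance, so it is exactly χ²(1) under the null and invariant to rescaling
w. The denominator is the quadratic form wᵀRw (not its square root): this
is the only reading that yields a calibrated 1-df statistic, which the null
simulations confirm (P-value uniformity by Kolmogorov–Smirnov at 2,000
null genes). Monomorphic panel SNPs receive zero weight; gene–tissue pairs
with wᵀRw ≤ 1e-12 are skipped and logged; weight rows are themselves
harmonized to the panel orientation before use.

Genomic control follows the conventional recipe: λ = median(χ²)/0.456 per
tissue, applied (χ² divided by λ) only when λ > 1.05. The constant 0.456
is the field's traditional rounding of the exact χ²(1) median
Φ⁻¹(0.75)² = 0.45494 (from 0.675² = 0.4556); the package keeps the
conventional value, 0.23% above the exact median. Note that under a
polygenic architecture λ legitimately exceeds 1 — genomic control then
deflates true signal as well as confounding; this is faithful to the
procedure being modelled and visible in the spiked scenario (λ ≈ 2–3).
P-values are floored at 1e-300. Six sex-specific tissue names
(breast mammary tissue, ovary, prostate, testis, uterus, vagina) are
provided as the default exclusion list for mixed-sex GWAS integration.

## Harmonic-mean P-value combination

For K per-tissue P-values with non-negative weights summing to one
(equal weights by default and throughout the tests), the harmonic mean
T = 1/(Σ ωₖ/Pₖ) has reciprocal 1/T asymptotically Landau-distributed under
the null, with location ln K + 0.874 and scale π/2. The constant 0.874
equals ln(π/2) + 1 − γ (Euler–Mascheroni). The "log" in the location is
the natural log of K, the number of tests — a location depending on the
observed statistic would define no valid test.

Parameterization: the Landau distribution here is the α = 1, β = 1 stable
law exactly as implemented by `scipy.stats.landau`; the classic Landau
density integral f(u) = (1/π)∫₀^∞ exp(−t ln t − ut) sin(πt) dt corresponds
to it through the affine map u = (π/2)x + ln(π/2). The choice is forced by
calibration: with K = 1 the combined P-value must reproduce the input
P-value, which holds in this parameterization (relative error < 0.5% for
p ≤ 1e-4) and fails by a factor ≈ π/2 in the other. The calibration is
tail-asymptotic: the K = 1 deviation grows to ≈ 0.03 in absolute terms by
p = 0.5, and the type-I error under 40 tests sharing pairwise correlation
0.8 is ≈ 0.045 at α = 0.05 (10,000 replicates) — slightly conservative,
as expected under strong positive dependence. The small-K exact-test
refinement of the HMP is not implemented; the Landau-tail version is the
one used throughout.

## Conditional and conjunction FDR

The conditional FDR is the standard empirical-Bayes plug-in
min(1, pᵢ · #{Pⱼ ≤ pⱼ} / #{Pᵢ ≤ pᵢ and Pⱼ ≤ pⱼ}), evaluated at each
gene's own observed pair over the common gene universe, ties counted
inclusively; the denominator is at least 1 because the gene itself
qualifies. No grid evaluation, interpolation or monotone regularization is
applied — the simplest faithful estimator. Conditioning on nothing
(pⱼ ≡ 1) reduces it to the Benjamini–Hochberg quantity pᵢ·N/rank(pᵢ),
which the tests verify, and the whole estimator is checked exactly against
an O(N²) brute-force count. The conjunction ccFDR is the element-wise max
of the two directions; all selection thresholds use strict `<` at
α = 0.05. Conditional Q–Q tables stratify the principal trait's P-values
at conditioning thresholds {1, 0.1, 0.01, 0.001} (descending, the first
stratum containing all genes, strata nested), with expected quantiles
k/(n+1); the leftward-shift statistic is the difference in mean observed
−log₁₀ P between the most stringent non-empty stratum and the
unconditional one.

A note on the published 14-gene worked-example table shipped in
`pleioscan.datasets`: for most rows the published conjunction value does
not equal the maximum of the two published conditional FDRs (MAGI3 is the
exception). The package implements the definition literally; the
decision-rule check (all 14 genes pass ccFDR < 0.05) holds under both the
published values and the recomputed maximum.

## Characterization of detected genes

Per-gene cross-trait effect correlation: Pearson r over the gene's shared
cis-SNPs (the weighted set by default; the full cis window is available
via the gene SNP sets argument), using β when present and z/√n otherwise
(per-trait scaling leaves r unchanged), with 95% Fisher-z intervals
tanh(atanh r ± 1.96/√(n−3)); at least 3 SNPs required. Genetic risk
scores are unstandardized sums of dosage × effect over the gene's SNPs on
the harmonized orientation, reported per panel individual and as the mean;
the trait with the larger mean GRS is named per gene (raw means compared,
matching the literal "product of effect sizes and genotypes" description).

## Synthetic-data generator

What it emulates — and the defaults that define the standard scenario:

| parameter | default | role |
|---|---|---|
| n_individuals | 500 | reference-panel size (a 1000G-European-scale panel) |
| n_snps / block_size | 5,000 / 40 | genome of independent LD blocks |
| within_block_corr | 0.8 | AR(1) latent correlation inside a block |
| maf_range | (0.05, 0.5) | uniform allele-frequency spectrum |
| n_genes / n_tissues | 125 / 5 | contiguous cis windows; tissue panel |
| weight_sparsity | 0.3 | fraction of cis-SNPs weighted per tissue |
| cross_tissue_corr | 0.8 | correlation of a gene's weights across tissues |
| h2 (both traits) | 0.3 | SNP heritability |
| rg | 0.4 | genetic correlation |
| n_gwas (both) | 20,000 | GWAS sample sizes |
| prop_causal | 1.0 | polygenic background (infinitesimal model) |
| n_pleiotropic_genes | 12 | spiked shared genes |
| pleiotropic_boost | 25 | per-gene variance multiple of the spikes |

Genotypes: within each block a latent Gaussian with correlation ρ^|j−k| is
thresholded at the MAF quantile per haplotype; dosages are sums of two
independent haplotypes, so Hardy–Weinberg holds by construction. Blocks
are placed 10.2 Mb apart so the 10 Mb LD-score window never spans two
independent blocks — otherwise the sampling noise of ~5,000 adjusted-r²
cross-block terms (sd ≈ 0.2) would swamp the true LD-score spread and
attenuate the LDSC slope toward zero. The within-block correlation of 0.8
gives LD scores enough spread (≈ 1.1–3.0) to identify the regression
slope at desk scale.

Effects: all causal SNPs (a prop_causal subset, shared between traits)
carry bivariate-normal standardized effects with correlation rg.
Pleiotropic genes act through cis expression: each receives an effect
along its latent eQTL weight vector — the same latent its tissue weights
share — with total variance `pleiotropic_boost × block size` background
units and trait signs agreeing with probability (1 + rg)/2. This is the
TWAS generative mechanism, and it is what makes gene-level power
deterministic: an isotropic variance boost would leave the statistic's
alignment (wᵀμ)² a χ²(1) draw, and recall would be a coin flip once
genomic control absorbs the background. Variance units are renormalized so
each trait's per-SNP variances sum exactly to its h² (effect
conservation). Marginal Z-scores are drawn exactly from the LDSC sampling
model, per block: Z ~ MVN(√N·Rβ, R) with R the block's empirical panel
correlation.

What the generator does **not** emulate: realistic human MAF/LD spectra
(blocks are exchangeable and AR-structured), liability-threshold
case-control ascertainment (Z-scores are simulated on the observed linear
scale; the pipeline consumes Z-scores regardless of trait scale), sample
overlap between cohorts, population stratification, and elastic-net weight
training (weights are fabricated with the correct structural role).
Passing tests therefore demonstrate internal statistical correctness and
calibration of the pipeline, not robustness to the confounders of real
data.

Determinism: the panel, the gene latents, the summary statistics and the
tissue noise each use an independent child stream of the single seed, so
identical (config, seed) reproduce bit-identical outputs and each
generation step is individually reproducible.

## Numerical choices

P-values are floored at 1e-300 everywhere; Cholesky factorizations add
1e-8 to 1e-10 jitter on the diagonal; monomorphic SNPs get identity LD
rows and zero weight; empty Q–Q strata are omitted with a warning; QC of
an entire table down to zero records is a warning, not an error; jackknife
block counts reduce automatically (with a warning) when SNPs are fewer
than blocks. The λ threshold (1.05), the ccFDR significance level (0.05)
and the Q–Q thresholds are configurable arguments with the conventional
defaults stated above.

## Problem sizes

The test suite and the acceptance script run at the scales stated in the
scenario table: 5,000 SNPs / 20,000 GWAS samples for LDSC recovery
(pure polygenic variant of the default scenario), the spiked default for
ccFDR recovery, 2,000 null genes for calibration, and 10,000 replicates
for the HMP type-I simulations. These sizes were chosen so the median-based
λ check has a sampling SD of ~0.03 and the whole suite completes in well
under a minute of simulation time per scenario.

## Known limitations

Jackknife SEs are approximate when LD blocks exceed jackknife blocks (see
above). The empirical cFDR is evaluated pointwise and not monotone-
regularized, so estimates at neighbouring genes can cross. The genetic
correlation's sampling error at 5,000 SNPs is substantial (se ≈ 0.2);
recovery is assessed against jackknife intervals, not point equality. The
per-tissue λ correction deflates true polygenic signal by design. The
reader-facing PLINK support covers variant-major bed files without missing
genotypes — sufficient for reference panels, not general cohort data.
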