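# pleioscan

Cross-trait pleiotropy analysis from GWAS summary statistics.

Many pairs of complex diseases — autoimmune diseases in particular — share
genetic etiology. Given only *summary statistics* from two genome-wide
association studies (per-SNP Z-scores, sample sizes and P-values), a
reference genotype panel for linkage disequilibrium (LD), and pre-trained
per-tissue eQTL weights, `pleioscan` answers three questions:

1. **How genetically similar are the traits?** Cross-trait LD-score
   regression (LDSC): regress χ²ⱼ = zⱼ² on *N*ℓⱼ/*M* to estimate SNP
   heritability *h*², and z₁ⱼz₂ⱼ on √(N₁N₂)ℓⱼ/*M* to estimate the genetic
   covariance, where ℓⱼ = Σₖ r²ⱼₖ is SNP *j*'s LD score. The genetic
   correlation is r_g = gencov/√(h₁²h₂²), with block-jackknife standard
   errors; a free intercept absorbs sample overlap.
2. **Which genes drive each trait?** For gene weights **w** (one vector per
   tissue) and cis-SNP Z-scores **Z**, the eQTL-weighted statistic
   χ² = (**Zw**ᵀ)²/(**w**R**w**ᵀ) is χ²(1 df) under the null (R = panel
   LD). Per-tissue genomic control divides by λ = median(χ²)/0.456 when
   λ > 1.05. The K correlated per-tissue P-values are combined by the
   harmonic-mean P-value: T = 1/(Σₖ ωₖ/Pₖ), with the calibrated P-value
   taken from the Landau-distribution upper tail at 1/T with location
   ln K + 0.874 and scale π/2 — valid under arbitrary positive dependence.
3. **Which genes affect *both* traits?** The conditional FDR
   cFDR(pᵢ|pⱼ) = Prob(H₀ᵢ | Pᵢ ≤ pᵢ, Pⱼ ≤ pⱼ), estimated by the empirical
   plug-in pᵢ·#{Pⱼ ≤ pⱼ}/#{both ≤}, in each direction; the conjunction
   ccFDR = max of the two flags pleiotropic genes (ccFDR < 0.05).

Real GWAS inputs at this scale are not redistributable, so the package
ships a first-class synthetic-data generator (`pleioscan.simulate`) that
emulates all three inputs with known ground truth — LD-blocked genotypes,
sparse tissue-correlated eQTL weights, and two-trait Z-scores drawn exactly
from the LDSC sampling model with chosen h², r_g and spiked pleiotropic
genes — so every stage of the pipeline is testable against truth.

## Worked example

```python
import pleioscan as ps

config = ps.SimulationConfig(seed=1, n_pleiotropic_genes=0)
panel = ps.generate_panel(config)
stats1, stats2, _ = ps.simulate_sumstats_pair(panel, config)
scores = ps.compute_ld_scores(panel)
rg = ps.estimate_rg(stats1, stats2, scores)
print(rg.rg, rg.se_rg, rg.p)
```

prints `0.512 0.213 0.016`: the estimated genetic correlation between the
two simulated traits (truth 0.4) with its jackknife standard error and the
two-sided P-value — a significantly positive shared genetic basis. The
single-trait regressions on the same data give h² = 0.274 (se 0.081) and
0.266 (se 0.084) against a simulated 0.3.

Running the full pleiotropy scan on the default spiked scenario
(`examples/05_pleiotropy_cfdr.py`, seed 42):

```
detected 12 pleiotropic genes at ccFDR < 0.05; 12 of 12 spiked genes
recovered (recall 100%, observed FDP 0%)
```

followed by a per-gene table of both conditional FDRs, the conjunction
ccFDR, the cross-trait Pearson correlation of SNP effect sizes with 95%
Fisher-z confidence intervals, and mean genetic risk scores (Σ dosage ×
effect) per trait over the panel individuals.

The `examples/` directory holds one short narrative script per capability:
data simulation, QC/harmonization, genetic correlation, gene association +
HMP combination, and the ccFDR pleiotropy scan.

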