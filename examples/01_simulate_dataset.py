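"""Generate a synthetic two-trait GWAS world with known ground truth.

Builds the default desk-scale scenario — a 500-individual reference panel,
5,000 SNPs in independent 40-SNP LD blocks, 125 genes in 5 tissues, two
GWAS of 20,000 samples with h2 = 0.3, rg = 0.4 and 12 spiked pleiotropic
genes — and writes the panel (PLINK bed/bim/fam), both summary-statistics
tables, the eQTL weights and the truth set to an output directory.
"""

from pathlib import Path

import pleioscan as ps
from pleioscan import plinkio
from pleioscan.simulate import write_sumstats, write_truth, write_weights

out = Path("scratch/example_data")
out.mkdir(parents=True, exist_ok=True)

config = ps.SimulationConfig(seed=42)
panel = ps.generate_panel(config)
weights = ps.generate_weights(panel, config)
stats1, stats2, truth = ps.simulate_sumstats_pair(panel, config)

plinkio.write_plink(panel, out / "panel")
write_sumstats(stats1, out / "trait1.sumstats.tsv")
write_sumstats(stats2, out / "trait2.sumstats.tsv")
write_weights(weights, out / "weights.tsv")
write_truth(truth, out / "pleiotropic_truth.tsv")

print(f"panel: {panel.n_individuals} individuals x {panel.n_snps} SNPs")
print(f"empirical MAF range: {panel.empirical_maf().min():.3f}"
      f" - {panel.empirical_maf().max():.3f}")
print(f"weights: {len(weights.genes)} genes x {len(weights.tissues)} tissues,"
      f" {len(weights.table)} nonzero entries")
print(f"mean chi2 trait 1: {(stats1['Z'] ** 2).mean():.2f}"
      " (inflation above 1 reflects the simulated polygenic signal)")
print(f"spiked pleiotropic genes: {', '.join(truth.pleiotropic_genes)}")
print(f"files written under {out}/")
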