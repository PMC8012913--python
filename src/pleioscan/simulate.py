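"""Synthetic GWAS world with known genetic architecture.

Generates the three inputs of the cross-trait pipeline with full ground
truth: an LD-structured reference genotype panel, sparse tissue-correlated
eQTL weights, and a pair of GWAS summary-statistic tables simulated under a
bivariate polygenic model with chosen heritabilities, genetic correlation
and a designated set of pleiotropic genes.

Model
-----
* Genotypes: within contiguous LD blocks a latent Gaussian with AR(1)
  correlation ``rho^|j-k|`` is thresholded, per haplotype, at the
  minor-allele-frequency quantile; dosages are the sum of two independent
  haplotypes, so Hardy-Weinberg holds by construction and blocks are
  mutually independent.
* Effects: a configurable fraction of SNPs is causal, shared between the two
  traits, with standardized effect pairs drawn from a bivariate normal with
  correlation ``rg``. Designated pleiotropic genes additionally act through
  their cis expression: each receives an effect proportional to the gene's
  latent eQTL weight vector (the same latent the tissue weights share), with
  total variance ``pleiotropic_boost`` times what an equally sized stretch
  of background SNPs carries, and with the two traits' effect signs agreeing
  with probability ``(1 + rg) / 2``. All variances are renormalized so each
  trait's total equals its configured h2.
* Marginal Z-scores: exactly, per LD block, ``Z ~ MVN(sqrt(N) R beta, R)``
  with ``R`` the block's empirical panel correlation — the sampling model
  that LD-score regression assumes.

Everything is deterministic given ``SimulationConfig.seed``; the panel,
weights and summary-statistic draws use separate child streams so each
operation is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

__all__ = [
    "SimulationConfig",
    "TissueWeightSet",
    "TruthSet",
    "generate_panel",
    "generate_weights",
    "simulate_sumstats_pair",
    "write_sumstats",
    "write_weights",
    "write_truth",
]

# non-complementary allele pairs, so no generated SNP is strand-ambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_BP_SPACING = 1_000  # SNPs sit 1 kb apart within an LD block
# LD blocks are placed >10 Mb apart so a 10 Mb LD-score window never spans
# two blocks; the generated map therefore realizes the block-independence
# the latent model asserts.
_BLOCK_SPACING = 10_200_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults define the package's standard desk-scale scenario: a 500-sample
    reference panel (the size of the 1000 Genomes European subset), 5,000
    SNPs in 40-SNP LD blocks, two GWAS of 20,000 samples each with h2 = 0.3
    per trait and genetic correlation 0.4, and 12 pleiotropic genes whose
    cis effects are 25-fold enriched.
    """

    n_individuals: int = 500
    n_snps: int = 5_000
    n_genes: int = 125
    n_tissues: int = 5
    block_size: int = 40
    within_block_corr: float = 0.8
    maf_range: tuple = (0.05, 0.5)
    h2_trait1: float = 0.3
    h2_trait2: float = 0.3
    rg: float = 0.4
    n_gwas1: int = 20_000
    n_gwas2: int = 20_000
    prop_causal: float = 1.0
    n_pleiotropic_genes: int = 12
    pleiotropic_boost: float = 25.0
    weight_sparsity: float = 0.3
    cross_tissue_corr: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for name in ("n_individuals", "n_snps", "n_genes", "n_tissues", "block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0 <= self.within_block_corr < 1):
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("h2_trait1", "h2_trait2"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (-1 <= self.rg <= 1):
            raise ValueError("rg must be in [-1, 1]")
        if not (0 < self.prop_causal <= 1):
            raise ValueError("prop_causal must be in (0, 1]")
        if not (0 < self.weight_sparsity <= 1):
            raise ValueError("weight_sparsity must be in (0, 1]")
        if not (0 <= self.cross_tissue_corr <= 1):
            raise ValueError("cross_tissue_corr must be in [0, 1]")
        if self.n_pleiotropic_genes > self.n_genes:
            raise ValueError("n_pleiotropic_genes cannot exceed n_genes")
        if self.n_snps // self.n_genes < 1:
            raise ValueError("need at least one SNP per gene window")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class TissueWeightSet:
    """Sparse per-gene, per-tissue cis-SNP eQTL weights.

    ``table`` is tidy with columns gene, tissue, snp, a1, a2, weight (only
    nonzero weights are stored); ``cis_sets`` maps each gene to the full
    list of SNP ids in its cis window, weighted or not.
    """

    table: pd.DataFrame
    cis_sets: dict

    @property
    def genes(self):
        return list(self.cis_sets)

    @property
    def tissues(self):
        return sorted(self.table["tissue"].unique())

    def weighted_sets(self) -> dict:
        """Gene -> SNP ids carrying a nonzero weight in any tissue."""
        g = self.table.groupby("gene")["snp"]
        return {gene: sorted(set(s)) for gene, s in g}


@dataclass
class TruthSet:
    """Ground truth of a simulated summary-statistics pair."""

    effects: pd.DataFrame  # snp, beta1, beta2 (standardized scale)
    pleiotropic_genes: list
    causal_snps: dict  # gene -> list of causal SNP ids in its window

    def is_pleiotropic(self, gene) -> bool:
        return gene in set(self.pleiotropic_genes)


def _block_bounds(n_snps: int, block_size: int):
    edges = list(range(0, n_snps, block_size)) + [n_snps]
    return list(zip(edges[:-1], edges[1:]))


def gene_windows(config: SimulationConfig) -> dict:
    """Contiguous, non-overlapping cis windows: gene -> SNP index range.

    The first ``n_genes * (n_snps // n_genes)`` SNPs are split evenly;
    trailing SNPs stay intergenic.
    """
    per_gene = config.n_snps // config.n_genes
    return {
        f"gene{g + 1}": (g * per_gene, (g + 1) * per_gene)
        for g in range(config.n_genes)
    }


def generate_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw an LD-blocked reference genotype panel.

    Within each block of ``block_size`` SNPs the latent haplotype process is
    AR(1) with parameter ``within_block_corr``; blocks are independent.
    """
    rng = np.random.default_rng([config.seed, 0])
    n, m = config.n_individuals, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.int8)
    for lo, hi in _block_bounds(m, config.block_size):
        bs = hi - lo
        rho = config.within_block_corr
        corr = rho ** np.abs(np.subtract.outer(np.arange(bs), np.arange(bs)))
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(bs))
        # two haplotypes per individual, independent given the LD structure
        latent = rng.standard_normal(size=(2 * n, bs)) @ chol.T
        alleles = (latent < thresholds[lo:hi]).astype(np.int8)
        dosages[:, lo:hi] = alleles[:n] + alleles[n:]

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    swap = rng.random(m) < 0.5
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    a1, a2 = np.where(swap, a2, a1), np.where(swap, a1, a2)

    pos = np.empty(m, dtype=np.int64)
    for b, (lo, hi) in enumerate(_block_bounds(m, config.block_size)):
        pos[lo:hi] = b * _BLOCK_SPACING + np.arange(1, hi - lo + 1) * _BP_SPACING

    snps = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": pos,
            "a1": a1,
            "a2": a2,
            "maf": mafs,
        }
    )
    return GenotypePanel(dosages=dosages, snps=snps)


def _gene_latents(config: SimulationConfig) -> dict:
    """Per-gene sparse support and latent eQTL weight vector.

    Drawn from a dedicated child stream of the seed so that both the tissue
    weights and the expression-mediated effects of pleiotropic genes can
    reconstruct the identical latents independently.
    """
    rng = np.random.default_rng([config.seed, 1])
    windows = gene_windows(config)
    latents = {}
    for gene, (lo, hi) in windows.items():
        m = hi - lo
        if m == 0:
            raise ValueError(f"{gene} has zero cis-SNPs")
        k = max(1, math.ceil(config.weight_sparsity * m))
        support = np.sort(rng.choice(m, size=k, replace=False))
        shared = rng.standard_normal(k)
        latents[gene] = (support, shared)
    return latents


def generate_weights(panel: GenotypePanel, config: SimulationConfig) -> TissueWeightSet:
    """Fabricate sparse eQTL weights with controlled cross-tissue sharing.

    Per gene, the latent weight vector on a common sparse support is mixed
    with independent tissue noise so that the expected correlation between
    any two tissues' weight vectors is ``cross_tissue_corr``. Every tissue
    keeps at least one nonzero weight per gene.
    """
    rng = np.random.default_rng([config.seed, 3])
    windows = gene_windows(config)
    latents = _gene_latents(config)
    c = config.cross_tissue_corr
    tissues = [f"tissue{t + 1}" for t in range(config.n_tissues)]

    rows = []
    cis_sets = {}
    for gene, (lo, hi) in windows.items():
        snp_ids = panel.snps["snp"].values[lo:hi]
        cis_sets[gene] = list(snp_ids)
        support, shared = latents[gene]
        k = len(support)
        sub = panel.snps.iloc[lo:hi].iloc[support]
        for tissue in tissues:
            noise = rng.standard_normal(k)
            w = math.sqrt(c) * shared + math.sqrt(1.0 - c) * noise
            w[w == 0.0] = 1e-6  # keep the sparsity contract exact
            for snp, a1, a2, wj in zip(sub["snp"], sub["a1"], sub["a2"], w):
                rows.append((gene, tissue, snp, a1, a2, wj))

    table = pd.DataFrame(
        rows, columns=["gene", "tissue", "snp", "a1", "a2", "weight"]
    )
    return TissueWeightSet(table=table, cis_sets=cis_sets)


def simulate_sumstats_pair(panel: GenotypePanel, config: SimulationConfig):
    """Simulate two GWAS summary-statistic tables plus their ground truth.

    Returns ``(stats1, stats2, truth)`` where each stats table has columns
    SNP, CHR, POS, A1, A2, Z, N, P with effect alleles oriented to the
    panel's alternate allele.

    The total effect variance is partitioned in units: each background
    causal SNP carries one unit, and each pleiotropic gene carries
    ``pleiotropic_boost * len(cis window)`` units concentrated along its
    normalized latent eQTL vector; units are scaled so each trait's
    variances sum to its h2 exactly.
    """
    if panel.n_snps != config.n_snps:
        raise ValueError("panel and config disagree on the number of SNPs")
    rng = np.random.default_rng([config.seed, 2])
    m = config.n_snps
    windows = gene_windows(config)
    genes = list(windows)
    pleio = sorted(
        rng.choice(genes, size=config.n_pleiotropic_genes, replace=False)
    ) if config.n_pleiotropic_genes else []

    n_causal = max(1, round(config.prop_causal * m))
    causal = np.zeros(m, dtype=bool)
    causal[rng.choice(m, size=n_causal, replace=False)] = True

    gene_units = {
        g: config.pleiotropic_boost * (windows[g][1] - windows[g][0]) for g in pleio
    }
    unit_var = 1.0 / (n_causal + sum(gene_units.values()))
    sigma2_1 = config.h2_trait1 * unit_var * causal
    sigma2_2 = config.h2_trait2 * unit_var * causal
    if max(sigma2_1.max(), sigma2_2.max(), 0) > 1:
        raise ValueError(
            "per-SNP effect variance exceeds 1; lower h2 or raise prop_causal"
        )

    x = rng.standard_normal(m)
    y = rng.standard_normal(m)
    rg = config.rg
    beta1 = np.sqrt(sigma2_1) * x
    beta2 = np.sqrt(sigma2_2) * (rg * x + math.sqrt(1.0 - rg * rg) * y)

    # expression-mediated pleiotropic effects along each gene's latent
    # eQTL direction; the two traits' signs agree with prob (1 + rg) / 2
    latents = _gene_latents(config)
    for gene in pleio:
        lo, _ = windows[gene]
        support, shared = latents[gene]
        direction = shared / np.linalg.norm(shared)
        sign1 = rng.choice([-1.0, 1.0])
        sign2 = sign1 if rng.random() < (1.0 + rg) / 2.0 else -sign1
        for h2, sign, beta in (
            (config.h2_trait1, sign1, beta1),
            (config.h2_trait2, sign2, beta2),
        ):
            gamma = sign * math.sqrt(h2 * unit_var * gene_units[gene])
            beta[lo + support] += gamma * direction

    z1 = np.empty(m)
    z2 = np.empty(m)
    sqn1, sqn2 = math.sqrt(config.n_gwas1), math.sqrt(config.n_gwas2)
    for lo, hi in _block_bounds(m, config.block_size):
        bs = hi - lo
        X = panel.dosages[:, lo:hi].astype(float)
        sd = X.std(axis=0)
        R = np.eye(bs)
        ok = sd > 0
        if ok.any():
            sub = np.corrcoef(X[:, ok], rowvar=False)
            sub = np.atleast_2d(sub)
            idx = np.flatnonzero(ok)
            R[np.ix_(idx, idx)] = sub
        chol = np.linalg.cholesky(R + 1e-8 * np.eye(bs))
        e1 = chol @ rng.standard_normal(bs)
        e2 = chol @ rng.standard_normal(bs)
        z1[lo:hi] = sqn1 * (R @ beta1[lo:hi]) + e1
        z2[lo:hi] = sqn2 * (R @ beta2[lo:hi]) + e2

    def _table(z, n):
        return pd.DataFrame(
            {
                "SNP": panel.snps["snp"].values,
                "CHR": panel.snps["chrom"].values,
                "POS": panel.snps["pos"].values,
                "A1": panel.snps["a1"].values,
                "A2": panel.snps["a2"].values,
                "Z": z,
                "N": n,
                "P": np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
            }
        )

    snp_ids = panel.snps["snp"].values
    spiked = {g: set(windows[g][0] + latents[g][0]) for g in pleio}
    causal_by_gene = {
        gene: [
            snp_ids[j]
            for j in range(lo, hi)
            if causal[j] or j in spiked.get(gene, ())
        ]
        for gene, (lo, hi) in windows.items()
    }
    truth = TruthSet(
        effects=pd.DataFrame({"snp": snp_ids, "beta1": beta1, "beta2": beta2}),
        pleiotropic_genes=list(pleio),
        causal_snps=causal_by_gene,
    )
    return _table(z1, config.n_gwas1), _table(z2, config.n_gwas2), truth


# ---------------------------------------------------------------------------
# plain-text writers (tab-delimited; the PLINK panel writer lives in plinkio)


def write_sumstats(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_weights(weights: TissueWeightSet, path) -> None:
    cols = ["gene", "tissue", "snp", "a1", "a2", "weight"]
    weights.table[cols].to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthSet, path) -> None:
    pd.DataFrame({"gene": truth.pleiotropic_genes}).to_csv(
        path, sep="\t", index=False
    )
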