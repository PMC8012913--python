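"""Post-hoc characterization of detected pleiotropic genes.

Two descriptive summaries: (1) the Pearson correlation, per gene, between
the two traits' per-SNP effect sizes over the gene's cis-SNP set, with 95%
Fisher-z confidence intervals; (2) per-gene genetic risk scores (GRS) over
the reference-panel individuals — for each trait the plain sum of dosage
times effect size across the gene's SNPs, on the harmonized allele
orientation.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)

MIN_SNPS_FOR_CORRELATION = 3


def _effect_sizes(stats_table: pd.DataFrame) -> pd.Series:
    """Per-SNP effect size: BETA when present, else Z / sqrt(N)."""
    if "BETA" in stats_table.columns:
        eff = stats_table["BETA"].astype(float)
    else:
        eff = stats_table["Z"].astype(float) / np.sqrt(stats_table["N"].astype(float))
    return pd.Series(eff.to_numpy(), index=stats_table["SNP"].to_numpy())


def effect_correlation(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    gene_snp_sets: dict,
) -> pd.DataFrame:
    """Cross-trait Pearson correlation of SNP effects, per gene.

    Both tables must share the harmonized allele orientation. Genes with
    fewer than 3 shared SNPs, or with a zero-variance effect vector, are
    omitted with a warning. The 95% CI is ``tanh(atanh(r) +/- 1.96 /
    sqrt(n - 3))``.
    """
    e1 = _effect_sizes(stats1)
    e2 = _effect_sizes(stats2)
    shared = set(e1.index) & set(e2.index)

    rows = []
    for gene, snps in gene_snp_sets.items():
        ids = [s for s in snps if s in shared]
        if len(ids) < MIN_SNPS_FOR_CORRELATION:
            logger.warning("%s: only %d shared SNPs; omitted", gene, len(ids))
            continue
        x = e1.loc[ids].to_numpy()
        y = e2.loc[ids].to_numpy()
        if x.std() == 0 or y.std() == 0:
            logger.warning("%s: zero-variance effect vector; omitted", gene)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        n = len(ids)
        if abs(r) < 1.0 and n > 3:
            half = 1.96 / math.sqrt(n - 3)
            lo, hi = math.tanh(math.atanh(r) - half), math.tanh(math.atanh(r) + half)
        else:
            lo = hi = r
        rows.append((gene, n, r, lo, hi))
    return pd.DataFrame(rows, columns=["gene", "n_snps", "r", "ci_low", "ci_high"])


def compute_grs(
    panel: GenotypePanel,
    stats_table: pd.DataFrame,
    gene_snp_sets: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene genetic risk scores over panel individuals.

    Returns ``(scores, summary)``: ``scores`` is genes x individuals,
    ``summary`` has one row per gene with its mean GRS. SNPs absent from
    the panel or the summary statistics are skipped (counted); genes with
    no usable SNP are omitted with a warning.
    """
    eff = _effect_sizes(stats_table)
    score_rows = {}
    n_skipped = 0
    for gene, snps in gene_snp_sets.items():
        usable = [s for s in snps if s in panel and s in eff.index]
        n_skipped += len(snps) - len(usable)
        if not usable:
            logger.warning("%s: no usable SNPs for GRS; omitted", gene)
            continue
        dos = panel.dosage_for(usable)
        score_rows[gene] = dos @ eff.loc[usable].to_numpy()
    if n_skipped:
        logger.info("GRS skipped %d SNPs absent from panel or stats", n_skipped)

    scores = pd.DataFrame.from_dict(score_rows, orient="index")
    scores.index.name = "gene"
    summary = pd.DataFrame(
        {"gene": scores.index, "mean_grs": scores.mean(axis=1).to_numpy()}
    ).reset_index(drop=True)
    return scores, summary


def summarize(
    cfdr_table: pd.DataFrame,
    corr_table: pd.DataFrame,
    grs_summary1: pd.DataFrame,
    grs_summary2: pd.DataFrame,
    trait_names=("trait1", "trait2"),
) -> pd.DataFrame:
    """One row per pleiotropic gene: FDR estimates, effect correlation, GRS.

    The ``higher_grs`` column names the trait with the larger mean GRS.
    """
    pleio = cfdr_table[cfdr_table["pleiotropic"]].copy()
    if len(pleio) == 0:
        return pd.DataFrame(
            columns=[
                "gene", "p_trait1", "p_trait2", "cfdr_1_given_2",
                "cfdr_2_given_1", "ccfdr", "n_snps", "r", "ci_low", "ci_high",
                "mean_grs_trait1", "mean_grs_trait2", "higher_grs",
            ]
        )
    out = pleio[
        ["gene", "p_trait1", "p_trait2", "cfdr_1_given_2", "cfdr_2_given_1", "ccfdr"]
    ].merge(corr_table, on="gene", how="left")
    out = out.merge(
        grs_summary1.rename(columns={"mean_grs": "mean_grs_trait1"}), on="gene", how="left"
    ).merge(
        grs_summary2.rename(columns={"mean_grs": "mean_grs_trait2"}), on="gene", how="left"
    )
    with np.errstate(invalid="ignore"):
        out["higher_grs"] = np.where(
            out["mean_grs_trait1"].to_numpy() >= out["mean_grs_trait2"].to_numpy(),
            trait_names[0],
            trait_names[1],
        )
    return out.reset_index(drop=True)
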