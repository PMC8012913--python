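"""eQTL-weighted gene-tissue association from GWAS summary statistics.

For a gene with cis-SNP Z-scores ``z``, tissue weight vector ``w`` and
reference LD matrix ``R``, the gene-tissue statistic is

    chi2 = (z . w)^2 / (w' R w)

which is chi-squared with 1 df under the null (the denominator is the
variance of the weighted Z-sum) and invariant to rescaling of ``w``.
Per-tissue genomic control divides all statistics of a tissue by
``lambda = median(chi2) / 0.456`` whenever lambda exceeds 1.05; 0.456 is
the conventional null median of a 1-df chi-squared (the exact value is
``Phi^{-1}(0.75)^2 = 0.4549``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel
from .simulate import TissueWeightSet

logger = logging.getLogger(__name__)

#: Conventional expected median of a chi-squared(1) statistic under the null.
NULL_MEDIAN_CHI2 = 0.456

#: Genomic control is applied only when lambda exceeds this threshold.
GC_THRESHOLD = 1.05

#: Sex-specific tissues excluded from mixed-sex GWAS integration.
SEX_SPECIFIC_TISSUES = (
    "Breast_Mammary_Tissue",
    "Ovary",
    "Prostate",
    "Testis",
    "Uterus",
    "Vagina",
)

P_FLOOR = 1e-300


class StatisticUndefinedError(ValueError):
    """w'Rw is numerically zero; the gene-tissue statistic does not exist."""


@dataclass
class LDMatrix:
    """Cis-SNP LD: ordered ids plus their panel correlation matrix."""

    snp_ids: list
    R: np.ndarray
    monomorphic: list

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("LD matrix shape does not match the SNP list")


@dataclass
class InflationFactor:
    lambda_: float
    applied: bool
    n_stats: int


def build_ld_matrix(panel: GenotypePanel, snp_ids) -> LDMatrix:
    """Pearson correlation of panel dosage columns, in the given SNP order.

    Monomorphic SNPs get an identity row/column and are flagged; they carry
    no signal and should receive zero weight downstream.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("need at least one SNP")
    X = panel.dosage_for(snp_ids)
    sd = X.std(axis=0)
    mono = [s for s, v in zip(snp_ids, sd) if v == 0]
    m = len(snp_ids)
    R = np.eye(m)
    ok = sd > 0
    if ok.sum() >= 2:
        idx = np.flatnonzero(ok)
        sub = np.corrcoef(X[:, idx], rowvar=False)
        R[np.ix_(idx, idx)] = sub
    np.fill_diagonal(R, 1.0)
    return LDMatrix(snp_ids=snp_ids, R=R, monomorphic=mono)


def gene_tissue_stat(z, w, R) -> float:
    """The weighted chi-squared statistic ``(z.w)^2 / (w'Rw)``."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    Rm = R.R if isinstance(R, LDMatrix) else np.asarray(R, dtype=float)
    if not (len(z) == len(w) == Rm.shape[0]):
        raise ValueError("z, w and R dimensions disagree")
    denom = float(w @ Rm @ w)
    if denom <= 1e-12:
        raise StatisticUndefinedError(f"w'Rw = {denom:g}")
    return float((z @ w) ** 2 / denom)


def estimate_lambda(chi2_values, threshold: float = GC_THRESHOLD) -> InflationFactor:
    """Genomic inflation factor: median observed chi2 over the null 0.456."""
    vals = np.asarray(chi2_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite chi-squared statistics")
    lam = float(np.median(vals) / NULL_MEDIAN_CHI2)
    return InflationFactor(lambda_=lam, applied=lam > threshold, n_stats=vals.size)


def apply_genomic_control(
    table: pd.DataFrame, inflation: InflationFactor
) -> pd.DataFrame:
    """Divide raw statistics by lambda when applied; recompute P-values."""
    out = table.copy()
    lam = inflation.lambda_ if inflation.applied else 1.0
    out["lambda"] = inflation.lambda_
    out["chi2_corrected"] = out["chi2_raw"] / lam
    out["p"] = np.clip(stats.chi2.sf(out["chi2_corrected"], df=1), P_FLOOR, 1.0)
    return out


def run_multitissue(
    sumstats: pd.DataFrame,
    weights: TissueWeightSet,
    panel: GenotypePanel,
    excluded_tissues=(),
    gc_threshold: float = GC_THRESHOLD,
) -> pd.DataFrame:
    """Gene x tissue statistics for one trait, with per-tissue genomic control.

    ``sumstats`` must be harmonized to the panel orientation. Weight rows
    whose effect allele is the panel reference are sign-flipped; rows whose
    allele pair does not match the panel are dropped. Genes with no weighted
    SNP present in the summary statistics are omitted (counted in the log);
    monomorphic panel SNPs are given zero weight.
    """
    known = set(weights.table["tissue"].unique())
    for t in excluded_tissues:
        if t not in known:
            logger.warning("excluded tissue %r not present in the weight set", t)
    excluded = set(excluded_tissues)

    panel_idx = panel.snps.set_index("snp")
    z_by_snp = dict(zip(sumstats["SNP"], sumstats["Z"]))

    wt = weights.table[~weights.table["tissue"].isin(excluded)].copy()
    if wt.empty:
        logger.warning("all tissues excluded; empty result")
        return pd.DataFrame(
            columns=["gene", "tissue", "m_used", "chi2_raw", "lambda", "chi2_corrected", "p"]
        )

    # harmonize weight orientation to the panel
    pa1 = wt["snp"].map(panel_idx["a1"])
    pa2 = wt["snp"].map(panel_idx["a2"])
    same = (wt["a1"] == pa1) & (wt["a2"] == pa2)
    flip = (wt["a1"] == pa2) & (wt["a2"] == pa1)
    n_bad = int((~(same | flip)).sum())
    if n_bad:
        logger.warning("dropped %d weight rows with unmatched alleles", n_bad)
    wt = wt[same | flip].copy()
    wt.loc[flip[same | flip], "weight"] *= -1.0

    wt = wt[wt["snp"].isin(z_by_snp)]
    n_skipped_genes = 0
    ld_cache: dict = {}
    rows = []
    for (gene, tissue), sub in wt.groupby(["gene", "tissue"], sort=True):
        snp_ids = tuple(sub["snp"])
        if not snp_ids:
            continue
        if snp_ids not in ld_cache:
            ld_cache[snp_ids] = build_ld_matrix(panel, snp_ids)
        ld = ld_cache[snp_ids]
        w = sub["weight"].to_numpy(float).copy()
        if ld.monomorphic:
            w[np.isin(list(snp_ids), ld.monomorphic)] = 0.0
        z = np.array([z_by_snp[s] for s in snp_ids])
        try:
            chi2 = gene_tissue_stat(z, w, ld)
        except StatisticUndefinedError:
            logger.warning("skipping %s/%s: statistic undefined", gene, tissue)
            continue
        rows.append((gene, tissue, len(snp_ids), chi2))

    missing = set(weights.genes) - {r[0] for r in rows}
    n_skipped_genes = len(missing)
    if n_skipped_genes:
        logger.info("%d genes had no usable weighted SNPs", n_skipped_genes)

    raw = pd.DataFrame(rows, columns=["gene", "tissue", "m_used", "chi2_raw"])
    out = []
    for tissue, sub in raw.groupby("tissue", sort=True):
        inflation = estimate_lambda(sub["chi2_raw"], threshold=gc_threshold)
        out.append(apply_genomic_control(sub, inflation))
    return pd.concat(out, ignore_index=True) if out else raw
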