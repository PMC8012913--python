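"""Conditional and conjunction conditional FDR for two-trait pleiotropy.

The conditional FDR of a gene for the principal trait, given that both
traits' P-values fall at or below the gene's observed pair ``(p_i, p_j)``,
is estimated by the standard empirical-Bayes plug-in

    cFDR(p_i | p_j) = min(1, p_i * #{P_j <= p_j} / #{P_i <= p_i and P_j <= p_j})

evaluated at every gene's own pair over the common gene universe. The
conjunction statistic ccFDR = max of the two directional estimates flags
genes unlikely to be null for either trait. Conditioning on nothing
(``p_j = 1`` everywhere) recovers the familiar Benjamini-Hochberg quantity
``p_i * N / rank(p_i)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_QQ_THRESHOLDS = (1.0, 0.1, 0.01, 0.001)
P_FLOOR = 1e-300


def empirical_cfdr(p_principal, p_conditional) -> np.ndarray:
    """Plug-in conditional FDR estimate for every gene.

    Ties are counted inclusively (``<=``); the denominator is always >= 1
    because each gene qualifies at its own pair. Computed in chunks so the
    N^2 comparison never materializes a full boolean matrix.
    """
    pi = np.asarray(p_principal, dtype=float)
    pj = np.asarray(p_conditional, dtype=float)
    if pi.shape != pj.shape:
        raise ValueError("principal and conditional vectors differ in length")
    if ((pi <= 0) | (pi > 1) | (pj <= 0) | (pj > 1)).any():
        raise ValueError("P-values must lie in (0, 1]")
    pi = np.maximum(pi, P_FLOOR)
    pj = np.maximum(pj, P_FLOOR)

    n = pi.size
    out = np.empty(n)
    step = 1024
    for lo in range(0, n, step):
        hi = min(lo + step, n)
        below_j = pj[None, :] <= pj[lo:hi, None]  # genes qualifying on trait j
        both = below_j & (pi[None, :] <= pi[lo:hi, None])
        out[lo:hi] = pi[lo:hi] * below_j.sum(axis=1) / both.sum(axis=1)
    return np.minimum(out, 1.0)


def conjunction_ccfdr(cfdr_12, cfdr_21) -> np.ndarray:
    """Element-wise maximum of the two directional conditional FDRs."""
    a = np.asarray(cfdr_12, dtype=float)
    b = np.asarray(cfdr_21, dtype=float)
    if a.shape != b.shape:
        raise ValueError("cFDR vectors differ in length")
    return np.maximum(a, b)


def build_cfdr_table(
    genes, p_trait1, p_trait2, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Full per-gene record: both cFDRs, the ccFDR and the decision flags."""
    p1 = np.asarray(p_trait1, dtype=float)
    p2 = np.asarray(p_trait2, dtype=float)
    c12 = empirical_cfdr(p1, p2)
    c21 = empirical_cfdr(p2, p1)
    cc = conjunction_ccfdr(c12, c21)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "p_trait1": p1,
            "p_trait2": p2,
            "cfdr_1_given_2": c12,
            "cfdr_2_given_1": c21,
            "ccfdr": cc,
            "trait1_assoc": c12 < alpha,
            "trait2_assoc": c21 < alpha,
            "pleiotropic": cc < alpha,
        }
    )


def conditional_qq(
    p_principal,
    p_conditional,
    thresholds=DEFAULT_QQ_THRESHOLDS,
) -> tuple[pd.DataFrame, float]:
    """Stratified Q-Q table for conditional enrichment plots.

    For each conditioning threshold ``t`` (descending, first must be 1) the
    principal P-values of genes with conditional P <= t are sorted and
    paired with uniform expected quantiles ``k / (n_t + 1)``, both reported
    on the -log10 scale. Also returns the leftward-shift statistic: the mean
    observed -log10 P in the most stringent non-empty stratum minus that in
    the unconditional stratum. Empty strata are omitted with a warning.
    """
    thresholds = list(thresholds)
    if sorted(thresholds, reverse=True) != thresholds or thresholds[0] != 1:
        raise ValueError("thresholds must be descending and start at 1")
    pi = np.asarray(p_principal, dtype=float)
    pj = np.asarray(p_conditional, dtype=float)

    frames = []
    stratum_means = {}
    for t in thresholds:
        sel = np.sort(pi[pj <= t])
        if sel.size == 0:
            logger.warning("stratum for threshold %g is empty; omitted", t)
            continue
        expected = np.arange(1, sel.size + 1) / (sel.size + 1)
        obs = -np.log10(np.maximum(sel, P_FLOOR))
        frames.append(
            pd.DataFrame(
                {
                    "threshold": t,
                    "obs_neglog10": obs,
                    "exp_neglog10": -np.log10(expected),
                }
            )
        )
        stratum_means[t] = obs.mean()

    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["threshold", "obs_neglog10", "exp_neglog10"]
    )
    if len(stratum_means) >= 2:
        shift = stratum_means[min(stratum_means)] - stratum_means[max(stratum_means)]
    else:
        shift = float("nan")
    return table, float(shift)


def select_genes(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA):
    """Trait-1-associated, trait-2-associated and pleiotropic gene lists.

    Strict ``<`` comparisons throughout.
    """
    genes = records["gene"]
    list1 = list(genes[records["cfdr_1_given_2"] < alpha])
    list2 = list(genes[records["cfdr_2_given_1"] < alpha])
    list3 = list(genes[records["ccfdr"] < alpha])
    return list1, list2, list3
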