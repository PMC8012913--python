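"""Harmonic-mean P-value combination with the Landau-tail calibration.

A gene tested in K tissues yields K positively dependent P-values. Their
weighted harmonic mean ``T = 1 / (sum_k w_k / P_k)`` is anti-conservative
taken at face value, but under the generalized central limit theorem the
reciprocal ``1/T`` is asymptotically Landau-distributed under the null —
the alpha = 1, beta = 1 stable law — with location ``ln K + 0.874``
(0.874 = ln(pi/2) + 1 - Euler gamma) and scale ``pi/2`` for equal weights.
The combined P-value is the Landau upper tail at ``1/T``, and its
calibration is insensitive to positive dependence among the inputs.

``scipy.stats.landau`` implements exactly this stable-law parameterization
(it equals the classic Landau density integral composed with the affine map
``u -> (u - ln(pi/2)) / (pi/2)``).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import landau

HMP_LOCATION_OFFSET = 0.874  # ln(pi/2) + 1 - Euler-Mascheroni constant
P_FLOOR = 1e-300


def landau_upper_tail(x, loc: float = 0.0, scale: float = 1.0):
    """Upper-tail probability of the Landau distribution.

    Monotone non-increasing in ``x``; tends to 1 as ``x -> -inf``. Accepts
    scalars or arrays.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return landau.sf(x, loc=loc, scale=scale)


def _check_weights(k: int, weights):
    if weights is None:
        return np.full(k, 1.0 / k)
    w = np.asarray(weights, dtype=float)
    if w.shape != (k,):
        raise ValueError("weights must match the number of P-values")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return w


def harmonic_mean_p(p_values, weights=None) -> float:
    """Weighted harmonic mean ``1 / (sum_k w_k / p_k)`` (equal weights default)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("P-values must lie in (0, 1]")
    w = _check_weights(p.size, weights)
    return float(1.0 / np.sum(w / p))


def hmp_combined_p(p_values, weights=None) -> float:
    """Calibrated combined P-value for K dependent tests.

    ``landau_upper_tail(1/T, loc=ln K + 0.874, scale=pi/2)`` where T is the
    weighted harmonic mean; clipped into (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    t = harmonic_mean_p(p, weights)
    k = p.size
    tail = landau_upper_tail(
        1.0 / t, loc=math.log(k) + HMP_LOCATION_OFFSET, scale=math.pi / 2.0
    )
    return float(np.clip(tail, P_FLOOR, 1.0))


def combine_across_tissues(stats_table: pd.DataFrame) -> pd.DataFrame:
    """One combined P-value per gene from a gene x tissue P-value table.

    Expects columns ``gene`` and ``p`` (the output of the gene-association
    stage); extra grouping columns such as ``trait`` are respected if
    present. Genes observed in a single tissue pass through the K = 1 tail.
    """
    group_cols = ["trait", "gene"] if "trait" in stats_table.columns else ["gene"]
    rows = []
    for key, sub in stats_table.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        p = sub["p"].to_numpy(float)
        rows.append(
            (*key, p.size, harmonic_mean_p(p), hmp_combined_p(p))
        )
    return pd.DataFrame(rows, columns=[*group_cols, "K", "hmp", "p_combined"])
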