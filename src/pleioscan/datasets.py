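"""Small published reference tables used as worked-example inputs.

The pleiotropic-gene table below reproduces a published list of 14 genes
detected as associated with both rheumatoid arthritis (RA) and systemic
lupus erythematosus (SLE) by the conjunction conditional FDR at the 0.05
level, with each gene's two directional conditional FDRs and the published
ccFDR value. It serves as a printed-table input for worked examples and
decision-rule checks; note that for most rows the published ccFDR differs
from the maximum of the two printed cFDRs (MAGI3 is the exception), an
inconsistency in the original report that this package documents rather
than reproduces.
"""

from __future__ import annotations

import pandas as pd

_RA_SLE_ROWS = [
    # gene, chrom, start, end, cFDR_RA, cFDR_SLE, published ccFDR
    ("INPP5B", "1", 38_326_369, 38_412_729, 3.91e-16, 5.64e-3, 2.54e-2),
    ("OR5K2", "3", 98_216_448, 98_217_496, 1.42e-2, 9.12e-4, 4.63e-2),
    ("RP11-2C24.5", "16", 30_832_389, 30_833_431, 1.86e-2, 2.34e-16, 3.72e-2),
    ("CTD-3105H18.4", "19", 12_490_560, 12_494_501, 1.37e-2, 2.79e-4, 4.45e-2),
    ("MAGI3", "1", 113_933_371, 114_228_545, 1.81e-30, 1.60e-2, 1.60e-2),
    ("INPP1", "2", 191_208_196, 191_236_391, 7.07e-3, 5.79e-5, 4.24e-2),
    ("PDHB", "3", 58_413_357, 58_419_584, 2.51e-5, 5.66e-4, 6.60e-3),
    ("ITPR3", "6", 33_588_522, 33_664_351, 9.83e-27, 4.60e-4, 2.76e-3),
    ("CLIP2", "7", 73_703_803, 73_820_273, 4.88e-3, 7.32e-5, 3.09e-2),
    ("IRF5", "7", 128_577_666, 128_590_089, 5.45e-4, 4.27e-11, 2.72e-3),
    ("ICAM5", "19", 10_400_655, 10_407_453, 1.90e-3, 1.57e-4, 1.09e-2),
    ("TYK2", "19", 10_461_209, 10_491_352, 1.01e-6, 2.57e-5, 5.39e-4),
    ("CCDC116", "22", 21_987_007, 21_991_616, 1.06e-2, 3.38e-16, 3.18e-2),
    ("RP11-387H17.4", "17", 39_927_742, 39_939_601, 4.14e-5, 1.06e-4, 2.17e-3),
]

#: Number of genes in the published RA gene-based scan (Bonferroni base).
RA_SLE_N_GENES = 23_833


def ra_sle_pleiotropic_table() -> pd.DataFrame:
    """The published 14-gene RA/SLE pleiotropy table as a DataFrame."""
    return pd.DataFrame(
        _RA_SLE_ROWS,
        columns=[
            "gene",
            "chrom",
            "start",
            "end",
            "cfdr_trait1",
            "cfdr_trait2",
            "ccfdr_published",
        ],
    )
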