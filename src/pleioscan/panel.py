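"""Reference genotype panel container.

A :class:`GenotypePanel` holds a dosage matrix (individuals x SNPs, counting
copies of the alternate allele) together with a SNP map. It is the source of
all LD information used downstream: LD scores for the heritability and
genetic-correlation regressions, and cis-LD matrices for the eQTL-weighted
gene statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of the SNP map, in canonical order.
SNP_MAP_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]


@dataclass
class GenotypePanel:
    """Individuals x SNPs dosage matrix with per-SNP map information.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` array with values in ``[0, 2]``; entry
        ``(i, j)`` counts copies of the alternate allele ``a1`` of SNP ``j``
        carried by individual ``i``. No missing values.
    snps
        SNP map with columns ``snp`` (unique id), ``chrom``, ``pos``
        (1-based), ``a1`` (alternate / counted allele), ``a2`` (reference
        allele) and ``maf`` (the generating minor-allele frequency, or the
        empirical one for panels read from disk).
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError(
                f"SNP map has {len(self.snps)} rows but dosage matrix has "
                f"{self.dosages.shape[1]} columns"
            )
        if self.snps["snp"].duplicated().any():
            raise ValueError("panel SNP ids must be unique")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP map missing columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.snps["snp"])}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def indices(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids (KeyError if absent)."""
        return np.array([self._index[s] for s in snp_ids], dtype=int)

    def dosage_for(self, snp_ids) -> np.ndarray:
        """Dosage sub-matrix (individuals x len(snp_ids)) as float."""
        return self.dosages[:, self.indices(snp_ids)].astype(float)

    def alt_freq(self) -> np.ndarray:
        """Empirical alternate-allele frequency of every SNP."""
        return self.dosages.mean(axis=0) / 2.0

    def empirical_maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)
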