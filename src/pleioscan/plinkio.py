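"""Minimal PLINK 1 bed/bim/fam writer and reader for reference panels.

Only the variant-major .bed layout (magic ``6c 1b 01``) with no missing
genotypes is supported, which is all a simulated reference panel needs. The
.bim A1 column holds the counted (alternate) allele, matching the panel's
dosage convention; .fam individuals are synthetic placeholders.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit codes, variant-major: 00 hom A1 (dosage 2), 10 het, 11 hom A2, 01 missing
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = {0b00: 2, 0b10: 1, 0b11: 0}


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam from a panel."""
    prefix = Path(prefix)
    n, m = panel.n_individuals, panel.n_snps

    bim = pd.DataFrame(
        {
            "chrom": panel.snps["chrom"],
            "snp": panel.snps["snp"],
            "cm": 0,
            "pos": panel.snps["pos"],
            "a1": panel.snps["a1"],
            "a2": panel.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"I{i + 1}" for i in range(n)],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    dos = np.rint(panel.dosages).astype(int).T  # variant-major
    for d, c in _DOSAGE_TO_CODE.items():
        codes[dos == d] = c
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = codes[:, k::4]
        packed[:, : cols.shape[1]] |= cols << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypePanel:
    """Read ``prefix``.bed/.bim/.fam back into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)

    dosages = np.empty((n, m), dtype=np.int8)
    for k in range(4):
        idx = np.arange(k, n, 4)  # individuals stored in 2-bit slot k
        codes = (body[:, idx // 4] >> (2 * k)) & 0b11
        if (codes == 0b01).any():
            raise ValueError("missing genotypes are not supported")
        dec = np.empty_like(codes, dtype=np.int8)
        for c, d in _CODE_TO_DOSAGE.items():
            dec[codes == c] = d
        dosages[idx, :] = dec.T

    freq = dosages.mean(axis=0) / 2.0
    snps = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypePanel(dosages=dosages, snps=snps)
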