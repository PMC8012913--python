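"""Reading, quality control and allele harmonization of GWAS summary stats.

The QC follows the five-rule protocol standard for LD-score regression
inputs: (i) drop non-biallelic SNPs and strand-ambiguous (A/T, C/G) pairs;
(ii) drop duplicated ids and ids without an rs label; (iii) drop SNPs inside
excluded high-complexity regions (by default the MHC, chr6:28.5-33.3 Mb, and
chr8:7.2-12.5 Mb); (iv) keep only SNPs present in the reference panel;
(v) drop SNPs whose allele pair does not match the panel's. Each removed SNP
is attributed to the first rule that catches it, so the report's counts sum
to the input size.

After QC, :func:`harmonize_alleles` orients every record's effect to the
panel's alternate allele, flipping Z signs where needed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "Z", "N", "P"]

#: chrom, start, end (1-based, closed) of regions excluded from LDSC input.
DEFAULT_EXCLUDED_REGIONS = [
    ("6", 28_500_000, 33_300_000),  # major histocompatibility complex
    ("8", 7_200_000, 12_500_000),  # 8p23 inversion
]

_RS_PATTERN = re.compile(r"^rs\d+$")
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_BASES = {"A", "C", "G", "T"}


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics file lacks mandatory columns."""


@dataclass
class QCReport:
    """Per-rule removal counts; ``input = retained + sum(removals)``."""

    non_biallelic: int = 0
    strand_ambiguous: int = 0
    duplicated: int = 0
    no_rs_label: int = 0
    excluded_region: int = 0
    not_in_panel: int = 0
    allele_mismatch: int = 0
    retained: int = 0

    @property
    def n_input(self) -> int:
        d = asdict(self)
        return sum(d.values())

    @property
    def n_removed(self) -> int:
        return self.n_input - self.retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])


def read_sumstats(path, column_map=None, sep=r"\s+") -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical table.

    ``column_map`` maps canonical names (SNP, CHR, POS, A1, A2, Z, BETA, SE,
    N, P) to the file's column names; identity by default. Z is taken from a
    Z column when present, otherwise computed as BETA/SE. Rows whose numeric
    fields do not parse (including SE == 0) are dropped with a logged count.
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    present = {
        canon: column_map.get(canon, canon)
        for canon in ["SNP", "CHR", "POS", "A1", "A2", "Z", "BETA", "SE", "N", "P"]
        if column_map.get(canon, canon) in raw.columns
    }

    for required in ["SNP", "A1", "A2"]:
        if required not in present:
            raise SumstatsFormatError(f"missing mandatory column: {required}")
    if "Z" not in present and not ({"BETA", "SE"} <= present.keys()):
        raise SumstatsFormatError("need either a Z column or BETA and SE columns")

    out = pd.DataFrame({"SNP": raw[present["SNP"]].astype(str)})
    out["CHR"] = raw[present["CHR"]].astype(str) if "CHR" in present else "0"
    out["POS"] = (
        pd.to_numeric(raw[present["POS"]], errors="coerce") if "POS" in present else 0
    )
    out["A1"] = raw[present["A1"]].astype(str).str.upper()
    out["A2"] = raw[present["A2"]].astype(str).str.upper()

    if "Z" in present:
        out["Z"] = pd.to_numeric(raw[present["Z"]], errors="coerce")
    else:
        beta = pd.to_numeric(raw[present["BETA"]], errors="coerce")
        se = pd.to_numeric(raw[present["SE"]], errors="coerce")
        se = se.where(se > 0)
        out["Z"] = beta / se
    out["N"] = pd.to_numeric(raw[present["N"]], errors="coerce") if "N" in present else np.nan
    if "P" in present:
        out["P"] = pd.to_numeric(raw[present["P"]], errors="coerce")
    else:
        from scipy import stats

        out["P"] = 2.0 * stats.norm.sf(np.abs(out["Z"]))

    ok = out["Z"].notna() & np.isfinite(out["Z"])
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable or degenerate values", n_bad)
    return out[ok].reset_index(drop=True)


def _is_snp_allele(series: pd.Series) -> pd.Series:
    return series.str.len().eq(1) & series.isin(_BASES)


def apply_qc(
    table: pd.DataFrame,
    panel: GenotypePanel,
    excluded_regions=None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the five QC rules against a reference panel.

    Returns the filtered table plus a :class:`QCReport`; an empty result is
    a warning, not an error.
    """
    if excluded_regions is None:
        excluded_regions = DEFAULT_EXCLUDED_REGIONS
    df = table.reset_index(drop=True)
    report = QCReport()
    alive = np.ones(len(df), dtype=bool)

    def _remove(mask, rule):
        hit = mask.to_numpy(dtype=bool) & alive
        setattr(report, rule, getattr(report, rule) + int(hit.sum()))
        alive[hit] = False

    a1, a2 = df["A1"], df["A2"]
    _remove(~(_is_snp_allele(a1) & _is_snp_allele(a2)) | (a1 == a2), "non_biallelic")
    pairs = [frozenset(p) for p in zip(a1, a2)]
    _remove(pd.Series([p in _AMBIGUOUS for p in pairs]), "strand_ambiguous")
    _remove(df["SNP"].duplicated(keep=False), "duplicated")
    _remove(~df["SNP"].str.match(_RS_PATTERN), "no_rs_label")

    in_region = np.zeros(len(df), dtype=bool)
    chrom = df["CHR"].astype(str)
    pos = pd.to_numeric(df["POS"])
    for rchrom, start, end in excluded_regions:
        in_region |= ((chrom == str(rchrom)) & (pos >= start) & (pos <= end)).to_numpy()
    _remove(pd.Series(in_region), "excluded_region")

    _remove(~df["SNP"].isin(panel.snps["snp"]), "not_in_panel")

    panel_alleles = dict(
        zip(panel.snps["snp"], zip(panel.snps["a1"], panel.snps["a2"]))
    )
    mismatch = []
    for snp, x, y, live in zip(df["SNP"], a1, a2, alive):
        if not live:
            mismatch.append(False)
            continue
        pa = panel_alleles.get(snp)
        mismatch.append(pa is not None and {x, y} != set(pa))
    _remove(pd.Series(mismatch), "allele_mismatch")

    report.retained = int(alive.sum())
    out = df[alive].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("QC removed every SNP")
    return out, report


def harmonize_alleles(table: pd.DataFrame, panel: GenotypePanel) -> pd.DataFrame:
    """Orient all effects to the panel's alternate allele.

    Records whose effect allele already equals the panel alternate are kept
    as-is; records whose effect allele equals the panel reference get their
    Z sign flipped and alleles swapped; anything else is dropped (counted in
    the log). Input should already be panel-matched by :func:`apply_qc`.
    """
    df = table.reset_index(drop=True).copy()
    idx = panel.snps.set_index("snp")
    pa1 = df["SNP"].map(idx["a1"])
    pa2 = df["SNP"].map(idx["a2"])

    same = (df["A1"] == pa1) & (df["A2"] == pa2)
    flipped = (df["A1"] == pa2) & (df["A2"] == pa1)
    bad = ~(same | flipped)
    if bad.any():
        logger.warning("dropped %d records with unmatched alleles", int(bad.sum()))

    df.loc[flipped, "Z"] = -df.loc[flipped, "Z"]
    df.loc[flipped, ["A1", "A2"]] = df.loc[flipped, ["A2", "A1"]].to_numpy()
    return df[~bad].reset_index(drop=True)
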