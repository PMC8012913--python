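"""End-to-end synthetic pipeline: simulate -> QC -> LDSC -> gene tests ->
HMP -> conditional FDR -> pleiotropic gene recovery.

This is the orchestration layer used by the examples and the acceptance
script; every stage is the corresponding public function, so the pipeline
adds no behaviour of its own beyond wiring and bookkeeping against the
simulation's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cfdr as cfdr_mod
from . import gene_assoc, hmp, ldsc, report, sumstats
from .panel import GenotypePanel
from .simulate import (
    SimulationConfig,
    TissueWeightSet,
    TruthSet,
    generate_panel,
    generate_weights,
    simulate_sumstats_pair,
)


@dataclass
class PipelineResult:
    config: SimulationConfig
    panel: GenotypePanel
    weights: TissueWeightSet
    truth: TruthSet
    stats1: pd.DataFrame
    stats2: pd.DataFrame
    qc_report1: sumstats.QCReport
    qc_report2: sumstats.QCReport
    assoc1: pd.DataFrame
    assoc2: pd.DataFrame
    hmp1: pd.DataFrame
    hmp2: pd.DataFrame
    cfdr_table: pd.DataFrame
    gene_lists: tuple
    ldsc_result: object = None
    qq_shift_1_on_2: float = field(default=float("nan"))

    @property
    def pleiotropic_detected(self) -> list:
        return self.gene_lists[2]

    def recovery(self) -> dict:
        """Recall and observed false-discovery proportion vs the truth set."""
        truth = set(self.truth.pleiotropic_genes)
        found = set(self.pleiotropic_detected)
        tp = len(truth & found)
        recall = tp / len(truth) if truth else float("nan")
        fdp = (len(found) - tp) / len(found) if found else 0.0
        return {
            "n_true": len(truth),
            "n_detected": len(found),
            "n_recovered": tp,
            "recall": recall,
            "fdp": fdp,
        }


def run_pipeline(
    config: SimulationConfig,
    alpha: float = cfdr_mod.DEFAULT_ALPHA,
    run_ldsc: bool = True,
    excluded_tissues=(),
) -> PipelineResult:
    """Run the full synthetic analysis under one configuration."""
    panel = generate_panel(config)
    weights = generate_weights(panel, config)
    raw1, raw2, truth = simulate_sumstats_pair(panel, config)

    qc1, report1 = sumstats.apply_qc(raw1, panel)
    qc2, report2 = sumstats.apply_qc(raw2, panel)
    stats1 = sumstats.harmonize_alleles(qc1, panel)
    stats2 = sumstats.harmonize_alleles(qc2, panel)

    ldsc_result = None
    if run_ldsc:
        scores = ldsc.compute_ld_scores(panel)
        ldsc_result = ldsc.estimate_rg(stats1, stats2, scores)

    assoc1 = gene_assoc.run_multitissue(stats1, weights, panel, excluded_tissues)
    assoc2 = gene_assoc.run_multitissue(stats2, weights, panel, excluded_tissues)
    hmp1 = hmp.combine_across_tissues(assoc1)
    hmp2 = hmp.combine_across_tissues(assoc2)

    merged = hmp1[["gene", "p_combined"]].merge(
        hmp2[["gene", "p_combined"]], on="gene", suffixes=("_1", "_2")
    )
    table = cfdr_mod.build_cfdr_table(
        merged["gene"], merged["p_combined_1"], merged["p_combined_2"], alpha=alpha
    )
    lists = cfdr_mod.select_genes(table, alpha=alpha)
    _, shift = cfdr_mod.conditional_qq(
        merged["p_combined_1"].to_numpy(), merged["p_combined_2"].to_numpy()
    )

    return PipelineResult(
        config=config,
        panel=panel,
        weights=weights,
        truth=truth,
        stats1=stats1,
        stats2=stats2,
        qc_report1=report1,
        qc_report2=report2,
        assoc1=assoc1,
        assoc2=assoc2,
        hmp1=hmp1,
        hmp2=hmp2,
        cfdr_table=table,
        gene_lists=lists,
        ldsc_result=ldsc_result,
        qq_shift_1_on_2=shift,
    )


def characterize_pleiotropic(result: PipelineResult) -> pd.DataFrame:
    """Effect-size correlations and GRS summaries for the detected genes."""
    sets = {
        g: result.weights.weighted_sets()[g]
        for g in result.pleiotropic_detected
        if g in result.weights.cis_sets
    }
    corr = report.effect_correlation(result.stats1, result.stats2, sets)
    _, grs1 = report.compute_grs(result.panel, result.stats1, sets)
    _, grs2 = report.compute_grs(result.panel, result.stats2, sets)
    return report.summarize(result.cfdr_table, corr, grs1, grs2)
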