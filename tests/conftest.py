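import numpy as np
import pandas as pd
import pytest

import pleioscan as ps


@pytest.fixture(scope="session")
def tiny_config():
    return ps.SimulationConfig(
        n_individuals=80,
        n_snps=60,
        n_genes=6,
        n_tissues=3,
        block_size=10,
        n_pleiotropic_genes=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    return ps.generate_panel(tiny_config)


@pytest.fixture(scope="session")
def spiked_run():
    """Full pipeline under the default spiked scenario (no LDSC stage)."""
    return ps.run_pipeline(ps.SimulationConfig(seed=1), run_ldsc=False)


@pytest.fixture(scope="session")
def ldsc_recovery():
    """LD scores plus both traits' stats under the pure polygenic scenario."""
    cfg = ps.SimulationConfig(seed=1, n_pleiotropic_genes=0)
    panel = ps.generate_panel(cfg)
    s1, s2, _ = ps.simulate_sumstats_pair(panel, cfg)
    scores = ps.compute_ld_scores(panel)
    return cfg, panel, s1, s2, scores


def make_panel(dosages, chrom="1", pos=None, a1="A", a2="G"):
    """Hand-built panel from a dosage matrix, for targeted LD tests."""
    dosages = np.asarray(dosages)
    m = dosages.shape[1]
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "a1": a1,
            "a2": a2,
            "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
        }
    )
    return ps.GenotypePanel(dosages=dosages, snps=snps)
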