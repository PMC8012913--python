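"""Generator contracts: LD structure, weight sharing, effect architecture."""

import numpy as np
import pytest

import pleioscan as ps
from pleioscan.simulate import gene_windows


def _corr(panel):
    return np.corrcoef(panel.dosages.astype(float), rowvar=False)


class TestPanel:
    def test_determinism_same_seed(self, tiny_config):
        a = ps.generate_panel(tiny_config)
        b = ps.generate_panel(tiny_config)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snps.equals(b.snps)

    def test_different_seed_differs(self, tiny_config):
        a = ps.generate_panel(tiny_config)
        b = ps.generate_panel(tiny_config.with_seed(12))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_zero_corr_gives_independent_snps(self):
        cfg = ps.SimulationConfig(
            n_individuals=500, n_snps=100, n_genes=10, block_size=10,
            within_block_corr=0.0, n_pleiotropic_genes=0, seed=4,
        )
        r = _corr(ps.generate_panel(cfg))
        off = np.abs(r[np.triu_indices(100, k=1)])
        assert off.max() < 0.25

    def test_block_structure(self):
        cfg = ps.SimulationConfig(
            n_individuals=500, n_snps=60, n_genes=6, block_size=10,
            within_block_corr=0.9, n_pleiotropic_genes=0, seed=5,
        )
        r2 = _corr(ps.generate_panel(cfg)) ** 2
        within = [r2[j, j + 1] for j in range(59) if (j % 10) != 9]
        across = [
            r2[j, k]
            for j in range(60)
            for k in range(j + 1, 60)
            if j // 10 != k // 10
        ]
        assert np.mean(within) > np.mean(across)

    def test_maf_within_configured_range(self):
        cfg = ps.SimulationConfig(
            n_individuals=800, n_snps=200, n_genes=20, block_size=10,
            maf_range=(0.2, 0.4), n_pleiotropic_genes=0, seed=6,
        )
        panel = ps.generate_panel(cfg)
        maf = panel.empirical_maf()
        # binomial sampling tolerance around the drawn frequency
        assert (maf > 0.2 - 0.06).all() and (maf < 0.4 + 0.06).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ps.SimulationConfig(n_snps=0)
        with pytest.raises(ValueError):
            ps.SimulationConfig(rg=1.5)
        with pytest.raises(ValueError):
            ps.SimulationConfig(maf_range=(0.0, 0.5))


class TestWeights:
    def test_perfect_sharing(self, tiny_panel, tiny_config):
        from dataclasses import replace

        cfg = replace(tiny_config, weight_sparsity=1.0, cross_tissue_corr=1.0)
        w = ps.generate_weights(tiny_panel, cfg)
        for gene, sub in w.table.groupby("gene"):
            by_tissue = {
                t: s.sort_values("snp")["weight"].to_numpy()
                for t, s in sub.groupby("tissue")
            }
            vecs = list(by_tissue.values())
            for v in vecs[1:]:
                assert np.allclose(v, vecs[0])

    def test_zero_cross_tissue_correlation(self):
        cfg = ps.SimulationConfig(
            n_individuals=50, n_snps=2000, n_genes=200, n_tissues=2,
            block_size=10, weight_sparsity=1.0, cross_tissue_corr=0.0,
            n_pleiotropic_genes=0, seed=7,
        )
        panel = ps.generate_panel(cfg)
        w = ps.generate_weights(panel, cfg)
        corrs = []
        for gene, sub in w.table.groupby("gene"):
            piv = sub.pivot(index="snp", columns="tissue", values="weight")
            corrs.append(np.corrcoef(piv.T.to_numpy())[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_sparsity_contract(self):
        cfg = ps.SimulationConfig(
            n_individuals=50, n_snps=100, n_genes=10, block_size=10,
            weight_sparsity=0.3, n_pleiotropic_genes=0, seed=8,
        )
        panel = ps.generate_panel(cfg)
        w = ps.generate_weights(panel, cfg)
        counts = w.table.groupby(["gene", "tissue"]).size()
        assert (counts == 3).all()  # ceil(0.3 * 10), all weights nonzero
        assert (w.table["weight"] != 0).all()

    def test_weights_deterministic(self, tiny_panel, tiny_config):
        a = ps.generate_weights(tiny_panel, tiny_config)
        b = ps.generate_weights(tiny_panel, tiny_config)
        assert a.table.equals(b.table)


class TestSumstats:
    def test_null_model_is_standard_normal(self):
        cfg = ps.SimulationConfig(
            h2_trait1=0.0, h2_trait2=0.0, n_pleiotropic_genes=0, seed=9,
        )
        panel = ps.generate_panel(cfg)
        s1, s2, _ = ps.simulate_sumstats_pair(panel, cfg)
        for s in (s1, s2):
            chi2 = s["Z"].to_numpy() ** 2
            se = np.sqrt(2.0 / len(chi2))
            assert abs(chi2.mean() - 1.0) < 3 * se * 3  # LD inflates the SE

    def test_cross_trait_corr_increases_with_h2(self):
        corrs = []
        for h2 in (0.1, 0.3, 0.5):
            cfg = ps.SimulationConfig(
                h2_trait1=h2, h2_trait2=h2, rg=1.0,
                n_pleiotropic_genes=0, seed=10,
            )
            panel = ps.generate_panel(cfg)
            s1, s2, _ = ps.simulate_sumstats_pair(panel, cfg)
            corrs.append(np.corrcoef(s1["Z"], s2["Z"])[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]
        assert corrs[0] > 0

    def test_zero_rg_uncorrelated(self):
        cfg = ps.SimulationConfig(rg=0.0, n_pleiotropic_genes=0, seed=12)
        panel = ps.generate_panel(cfg)
        s1, s2, _ = ps.simulate_sumstats_pair(panel, cfg)
        assert abs(np.corrcoef(s1["Z"], s2["Z"])[0, 1]) < 0.05

    def test_effect_conservation(self):
        cfg = ps.SimulationConfig(prop_causal=0.5, n_pleiotropic_genes=0, seed=13)
        panel = ps.generate_panel(cfg)
        _, _, truth = ps.simulate_sumstats_pair(panel, cfg)
        total1 = (truth.effects["beta1"] ** 2).sum()
        total2 = (truth.effects["beta2"] ** 2).sum()
        assert total1 == pytest.approx(cfg.h2_trait1, rel=0.15)
        assert total2 == pytest.approx(cfg.h2_trait2, rel=0.15)

    def test_spiked_genes_carry_concentrated_effects(self, spiked_run):
        truth = spiked_run.truth
        eff = truth.effects.set_index("snp")
        windows = gene_windows(spiked_run.config)
        snp_ids = spiked_run.panel.snps["snp"].to_numpy()
        per_gene = {
            g: (eff.loc[snp_ids[lo:hi], "beta1"] ** 2).sum()
            for g, (lo, hi) in windows.items()
        }
        spiked = [per_gene[g] for g in truth.pleiotropic_genes]
        background = [
            v for g, v in per_gene.items() if not truth.is_pleiotropic(g)
        ]
        assert min(spiked) > max(background)

    def test_determinism(self, tiny_panel, tiny_config):
        a1, a2, _ = ps.simulate_sumstats_pair(tiny_panel, tiny_config)
        b1, b2, _ = ps.simulate_sumstats_pair(tiny_panel, tiny_config)
        assert a1.equals(b1) and a2.equals(b2)

    def test_p_matches_z(self, tiny_panel, tiny_config):
        from scipy import stats

        s1, _, _ = ps.simulate_sumstats_pair(tiny_panel, tiny_config)
        expect = 2 * stats.norm.sf(np.abs(s1["Z"]))
        assert np.allclose(s1["P"], np.clip(expect, 1e-300, 1))
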