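"""The eQTL-weighted gene-tissue statistic and genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pleioscan as ps
from pleioscan import gene_assoc
from pleioscan.gene_assoc import StatisticUndefinedError

from conftest import make_panel


class TestLDMatrix:
    def test_single_snp(self, tiny_panel):
        ld = ps.build_ld_matrix(tiny_panel, ["rs1"])
        assert ld.R.shape == (1, 1) and ld.R[0, 0] == 1.0

    def test_duplicated_column(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=300).astype(float)
        panel = make_panel(np.column_stack([col, col]))
        ld = ps.build_ld_matrix(panel, ["rs1", "rs2"])
        assert ld.R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_panel_near_identity(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.integers(0, 3, size=(500, 20)).astype(float))
        ld = ps.build_ld_matrix(panel, [f"rs{i + 1}" for i in range(20)])
        off = np.abs(ld.R[np.triu_indices(20, k=1)])
        assert off.mean() < 0.1
        assert np.allclose(ld.R, ld.R.T)
        assert np.allclose(np.diag(ld.R), 1.0)

    def test_monomorphic_flagged(self):
        rng = np.random.default_rng(3)
        dosages = rng.integers(0, 3, size=(100, 3)).astype(float)
        dosages[:, 1] = 2.0
        panel = make_panel(dosages)
        ld = ps.build_ld_matrix(panel, ["rs1", "rs2", "rs3"])
        assert ld.monomorphic == ["rs2"]
        assert ld.R[1, 0] == 0.0 and ld.R[1, 1] == 1.0


class TestStatistic:
    def test_single_snp_reduces_to_z_squared(self):
        assert ps.gene_tissue_stat([2.5], [1.0], np.eye(1)) == pytest.approx(6.25)

    def test_hand_computation(self):
        assert ps.gene_tissue_stat([1, 1], [1, 1], np.eye(2)) == pytest.approx(2.0)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal(5)
        w = rng.standard_normal(5)
        a = np.linalg.qr(rng.standard_normal((5, 5)))[0]
        R = a @ np.diag([2, 1, 1, 0.5, 0.5]) @ a.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        base = ps.gene_tissue_stat(z, w, R)
        for c in (2.0, -3.5, 1e-4):
            assert ps.gene_tissue_stat(z, c * w, R) == pytest.approx(base, rel=1e-10)

    def test_degenerate_denominator(self):
        with pytest.raises(StatisticUndefinedError):
            ps.gene_tissue_stat([1.0], [0.0], np.eye(1))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ps.gene_tissue_stat([1.0, 2.0], [1.0], np.eye(1))


class TestGenomicControl:
    def test_lambda_null_monte_carlo(self):
        rng = np.random.default_rng(5)
        draws = stats.chi2.rvs(df=1, size=10_000, random_state=rng)
        inf = ps.estimate_lambda(draws)
        assert inf.lambda_ == pytest.approx(1.0, abs=0.05)

    def test_lambda_at_null_median(self):
        inf = ps.estimate_lambda([0.456])
        assert inf.lambda_ == pytest.approx(1.0)
        assert not inf.applied

    def test_lambda_scale_equivariance(self):
        vals = [0.1, 0.5, 1.2, 3.0]
        a = ps.estimate_lambda(vals)
        b = ps.estimate_lambda([2 * v for v in vals])
        assert b.lambda_ == pytest.approx(2 * a.lambda_)

    def test_lambda_empty_errors(self):
        with pytest.raises(ValueError):
            ps.estimate_lambda([])

    def test_below_threshold_not_applied(self):
        table = pd.DataFrame({"gene": ["g"], "tissue": ["t"], "m_used": [1],
                              "chi2_raw": [3.0]})
        inf = gene_assoc.InflationFactor(lambda_=1.04, applied=False, n_stats=1)
        out = ps.apply_genomic_control(table, inf)
        assert out.loc[0, "chi2_corrected"] == 3.0

    def test_applied_division(self):
        table = pd.DataFrame({"gene": ["g"], "tissue": ["t"], "m_used": [1],
                              "chi2_raw": [3.0]})
        inf = gene_assoc.InflationFactor(lambda_=1.5, applied=True, n_stats=1)
        out = ps.apply_genomic_control(table, inf)
        assert out.loc[0, "chi2_corrected"] == pytest.approx(2.0)

    def test_p_from_chi2_quantile(self):
        table = pd.DataFrame({"gene": ["g"], "tissue": ["t"], "m_used": [1],
                              "chi2_raw": [3.841459]})
        inf = gene_assoc.InflationFactor(lambda_=1.0, applied=False, n_stats=1)
        out = ps.apply_genomic_control(table, inf)
        assert out.loc[0, "p"] == pytest.approx(0.05, abs=1e-6)

    def test_correction_never_increases(self, spiked_run):
        t = spiked_run.assoc1
        assert (t["chi2_corrected"] <= t["chi2_raw"] + 1e-12).all()


class TestMultitissue:
    def test_all_tissues_excluded(self, spiked_run):
        out = ps.run_multitissue(
            spiked_run.stats1,
            spiked_run.weights,
            spiked_run.panel,
            excluded_tissues=spiked_run.weights.tissues,
        )
        assert len(out) == 0

    def test_sex_specific_default_list(self):
        assert len(gene_assoc.SEX_SPECIFIC_TISSUES) == 6
        assert set(gene_assoc.SEX_SPECIFIC_TISSUES) == {
            "Breast_Mammary_Tissue", "Ovary", "Prostate", "Testis",
            "Uterus", "Vagina",
        }

    def test_spiked_gene_strongly_significant(self, spiked_run):
        truth = spiked_run.truth.pleiotropic_genes
        sub = spiked_run.assoc1[spiked_run.assoc1["gene"].isin(truth)]
        assert sub.groupby("gene")["p"].min().max() < 1e-4

    def test_tissue_weight_rescaling_changes_nothing(self, spiked_run):
        w = spiked_run.weights
        rescaled = ps.TissueWeightSet(table=w.table.copy(), cis_sets=w.cis_sets)
        mask = rescaled.table["tissue"] == "tissue1"
        rescaled.table.loc[mask, "weight"] *= 7.3
        a = ps.run_multitissue(spiked_run.stats1, w, spiked_run.panel)
        b = ps.run_multitissue(spiked_run.stats1, rescaled, spiked_run.panel)
        assert np.allclose(a["chi2_raw"], b["chi2_raw"], rtol=1e-10)

    def test_weight_orientation_flip_is_harmonized(self, spiked_run):
        w = spiked_run.weights
        flipped = w.table.copy()
        first = flipped.index[:100]
        flipped.loc[first, ["a1", "a2"]] = flipped.loc[first, ["a2", "a1"]].to_numpy()
        flipped.loc[first, "weight"] *= -1.0
        b = ps.run_multitissue(
            spiked_run.stats1,
            ps.TissueWeightSet(table=flipped, cis_sets=w.cis_sets),
            spiked_run.panel,
        )
        a = ps.run_multitissue(spiked_run.stats1, w, spiked_run.panel)
        assert np.allclose(a["chi2_raw"], b["chi2_raw"], rtol=1e-10)

    def test_unknown_excluded_tissue_warns_only(self, spiked_run, caplog):
        out = ps.run_multitissue(
            spiked_run.stats1, spiked_run.weights, spiked_run.panel,
            excluded_tissues=("no_such_tissue",),
        )
        assert len(out) > 0
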