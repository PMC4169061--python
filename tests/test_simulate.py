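"""Synthetic-cohort generator: marginal frequencies, LD, kinship, the
planted latent factor, and determinism."""

import numpy as np
import pandas as pd
import pytest

from micronet.metabolites import average_assessments, compute_met_pc
from micronet.simulate import SimConfig, simulate_genotypes, simulate_study


def _genotype_matrix(cfg):
    calls, quality, snp_map, gene_table, meta = simulate_genotypes(cfg)
    return calls.to_numpy(float), meta


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"n_subjects": 500, "n_families": 100},  # >3 per family
            {"within_block_r": 1.0},
            {"maf_range": (0.0, 0.3)},
            {"maf_range": (0.3, 0.6)},
            {"sbm_p_in": 0.01, "sbm_p_out": 0.05},
            {"causal_module_ids": (99,)},
            {"missing_call_rate": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenotypes:
    def test_allele_frequencies_match_target(self):
        """Sample MAF tracks the drawn population frequency within 3 binomial SE."""
        cfg = SimConfig(n_subjects=300, n_families=300, n_genes=60,
                        within_block_r=0.0, missing_call_rate=0.0,
                        low_quality_rate=0.0, seed=5)
        calls, _, snp_map, _, meta = simulate_genotypes(cfg)
        g = calls.to_numpy(float)
        f_hat = g.mean(axis=0) / 2
        f_pop = np.where(meta["freqs"] > 0.5, 1 - meta["freqs"], meta["freqs"])
        se = np.sqrt(f_pop * (1 - f_pop) / (2 * cfg.n_subjects))
        # oriented frequency compares to the folded population frequency
        assert (np.abs(f_hat - f_pop) < 3 * se + 1e-9).mean() > 0.97

    def test_hwe_proportions_at_half(self):
        """maf_range (0.5, 0.5) gives genotype frequencies ~ (1/4, 1/2, 1/4)."""
        cfg = SimConfig(n_subjects=600, n_families=600, n_genes=40,
                        maf_range=(0.5, 0.5), within_block_r=0.0,
                        missing_call_rate=0.0, low_quality_rate=0.0, seed=2)
        g, _ = _genotype_matrix(cfg)
        fracs = [(g == k).mean() for k in (0, 1, 2)]
        assert fracs[1] == pytest.approx(0.5, abs=0.02)
        assert fracs[0] == pytest.approx(0.25, abs=0.02)
        assert fracs[2] == pytest.approx(0.25, abs=0.02)

    def test_independent_snps_uncorrelated(self):
        """within_block_r = 0 leaves between-SNP correlation near zero."""
        cfg = SimConfig(n_subjects=500, n_families=500, n_genes=20,
                        within_block_r=0.0, missing_call_rate=0.0,
                        low_quality_rate=0.0, seed=3)
        g, _ = _genotype_matrix(cfg)
        c = np.corrcoef(g.T)
        off = c[np.triu_indices_from(c, k=1)]
        # null |r| at n=500 has SD ~ 0.045; essentially all pairs below 0.1
        assert (np.abs(off) < 0.1).mean() > 0.97
        assert np.abs(off).mean() < 0.05

    def test_adjacent_ld_matches_frozen_band(self):
        """seed=1, r=0.9, blocks of 10: mean adjacent r^2 in the band
        0.30-0.52 frozen from an independent copula simulation."""
        cfg = SimConfig(n_subjects=500, n_families=500, n_genes=20,
                        snps_per_gene=10, ld_block_size=10, within_block_r=0.9,
                        missing_call_rate=0.0, low_quality_rate=0.0, seed=1)
        calls, _, _, _, _ = simulate_genotypes(cfg)
        g = calls.to_numpy(float)
        r2 = []
        for b in range(0, g.shape[1], 10):
            c = np.corrcoef(g[:, b : b + 10].T)
            r2.extend(c[i, i + 1] ** 2 for i in range(9))
        assert 0.30 < np.mean(r2) < 0.52

    def test_siblings_more_correlated_than_strangers(self):
        cfg = SimConfig(n_subjects=300, n_families=100, n_genes=60, seed=4,
                        missing_call_rate=0.0, low_quality_rate=0.0)
        calls, _, _, _, meta = simulate_genotypes(cfg)
        g = calls.to_numpy(float)
        g = (g - g.mean(axis=0)) / np.maximum(g.std(axis=0), 1e-9)
        fam = np.asarray(meta["family_of"])
        cors = g @ g.T / g.shape[1]
        sib, stranger = [], []
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                (sib if fam[i] == fam[j] else stranger).append(cors[i, j])
        assert np.mean(sib) > np.mean(stranger) + 0.1

    def test_quality_and_missingness_rates(self):
        cfg = SimConfig(n_subjects=200, n_families=200, n_genes=100,
                        missing_call_rate=0.02, low_quality_rate=0.05, seed=6)
        calls, quality, _, _, _ = simulate_genotypes(cfg)
        miss = (calls.to_numpy() < 0).mean()
        assert miss == pytest.approx(0.02, abs=0.005)
        q = quality.to_numpy()
        low = (q[np.isfinite(q)] < 0.7).mean()
        assert low == pytest.approx(0.05, abs=0.01)
        # quality present wherever call present
        assert np.isnan(q[calls.to_numpy() < 0]).all()
        assert np.isfinite(q[calls.to_numpy() >= 0]).all()

    def test_last_block_truncated_not_error(self):
        cfg = SimConfig(n_subjects=50, n_families=50, n_genes=3,
                        snps_per_gene=7, ld_block_size=10, seed=0)
        calls, *_ = simulate_genotypes(cfg)
        assert calls.shape[1] == 21


class TestPhenotypes:
    def test_single_factor_limit(self):
        """No genetics, equal loadings, vanishing noise: metabolites are
        near-perfectly mutually correlated."""
        cfg = SimConfig(n_subjects=100, n_families=100, n_genes=20,
                        beta_snp=0.0, noise_sd=1e-6,
                        assessment_noise_frac=0.0,
                        metabolite_loadings={m: 1.0 for m in
                                             ("vitamin_A", "vitamin_E",
                                              "thiamine", "SAM_SAH")},
                        causal_module_ids=(1,), n_causal_genes=2, seed=8)
        s = simulate_study(cfg)
        wide = average_assessments(s.metabolites)
        corr = wide.corr().to_numpy()
        assert corr.min() > 0.999

    def test_pc1_share_matches_one_factor_closed_form(self):
        """k equal loadings with lambda=1, sigma=1: PC1 share -> 1/2."""
        cfg = SimConfig(n_subjects=500, n_families=500, n_genes=20,
                        beta_snp=0.0, noise_sd=1.0, assessment_noise_frac=0.0,
                        metabolite_loadings={f"m{i}": 1.0 for i in range(8)},
                        causal_module_ids=(1,), n_causal_genes=2, seed=9)
        s = simulate_study(cfg)
        wide = average_assessments(s.metabolites)
        pcs = compute_met_pc(wide, anchor="m0")
        assert pcs.variance_frac.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_pca_recovers_noise_free_latent(self, ):
        """Latent-factor recovery: |corr(PC1, L)| > 0.99 without noise."""
        cfg = SimConfig(n_subjects=200, n_families=130, noise_sd=1e-9,
                        n_genes=100, assessment_noise_frac=0.0, seed=10,
                        metabolite_loadings={m: 1.0 for m in
                                             ("vitamin_E", "thiamine",
                                              "pyridoxal", "SAM_SAH")})
        s = simulate_study(cfg)
        pcs = compute_met_pc(average_assessments(s.metabolites),
                             anchor="vitamin_E")
        L = s.truth["latent"]
        r = np.corrcoef(pcs.pc1.loc[L.index], L)[0, 1]
        assert abs(r) > 0.99

    def test_zero_causal_with_effect_is_error(self, small_config):
        from micronet.simulate import simulate_phenotypes

        cfg = small_config
        calls, _, snp_map, _, meta = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="causal"):
            simulate_phenotypes(cfg, calls, snp_map, {}, [],
                                meta["family_ids"])


class TestNetworkGeneration:
    def test_zero_out_probability_gives_disconnected_blocks(self):
        from micronet.simulate import simulate_network

        cfg = SimConfig(n_subjects=50, n_families=50, n_genes=100,
                        n_modules=2, sbm_p_in=0.3, sbm_p_out=1e-12,
                        causal_module_ids=(1,), n_causal_genes=3, seed=12)
        s = simulate_study(cfg)
        import networkx as nx

        comps = list(nx.connected_components(s.network))
        # near-zero out-probability: components align with the two blocks
        assert len(comps) >= 2

    def test_edge_count_near_sbm_expectation(self, small_study, small_config):
        cfg = small_config
        n_per = cfg.n_genes // cfg.n_modules
        exp_in = cfg.n_modules * n_per * (n_per - 1) / 2 * cfg.sbm_p_in
        n_cross = cfg.n_genes * (cfg.n_genes - 1) / 2 - cfg.n_modules * n_per * (n_per - 1) / 2
        expected = exp_in + n_cross * cfg.sbm_p_out
        se = np.sqrt(expected)
        assert abs(small_study.network.number_of_edges() - expected) < 4 * se

    def test_neighborhood_overlaps_designated_block(self, small_study):
        block = small_study.truth["neighborhood_block"]
        in_block = [g for g in small_study.neighborhood_genes
                    if small_study.truth["block_of"][g] == block]
        frac = len(in_block) / len(small_study.neighborhood_genes)
        assert frac == pytest.approx(0.7, abs=0.05)

    def test_truth_genes_exist_everywhere(self, small_study):
        genes = set(small_study.gene_table["gene_id"])
        assert set(small_study.truth["causal_genes"]) <= genes
        assert set(small_study.truth["causal_genes"]) <= set(
            small_study.network.nodes()
        )


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        pd.testing.assert_frame_equal(a.calls, b.calls)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.proteins, b.proteins)
        assert sorted(a.network.edges()) == sorted(b.network.edges())
        assert a.neighborhood_genes == b.neighborhood_genes
        pd.testing.assert_frame_equal(a.qtl_table, b.qtl_table)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        a = simulate_study(small_config)
        b = simulate_study(dataclasses.replace(small_config, seed=99))
        assert not a.calls.equals(b.calls)
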