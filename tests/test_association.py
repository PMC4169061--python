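"""Clustered SNP association: GEE/OLS equivalence, cross-check against
statsmodels GEE, BH arithmetic, calibration and recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from micronet.association import bh_adjust, fit_gee_snp, run_genome_scan
from tests.conftest import make_covariates


def toy_data(n=80, beta=0.4, seed=0, families=None):
    rng = np.random.default_rng(seed)
    cov = make_covariates(n, families=families, seed=seed)
    g = pd.Series(rng.binomial(2, 0.3, n), index=cov.index, name="rs1")
    y = pd.Series(
        beta * g + 0.05 * cov["age"] + rng.normal(size=n), index=cov.index,
        name="y",
    )
    return y, g, cov


class TestFitGeeSnp:
    def test_singleton_clusters_equal_ols(self):
        y, g, cov = toy_data(seed=1)
        res = fit_gee_snp(y, g, cov)
        x = sm.add_constant(
            np.column_stack([cov["age"], cov["sex"], cov["hei"], g])
        )
        ols = sm.OLS(y, x).fit()
        assert res.beta == pytest.approx(ols.params[-1], abs=1e-8)

    def test_matches_statsmodels_gee_with_families(self):
        """Independent cross-check: statsmodels GEE with independence
        working correlation and robust covariance."""
        fams = [f"f{i // 2}" for i in range(80)]
        y, g, cov = toy_data(seed=2, families=fams)
        res = fit_gee_snp(y, g, cov)
        x = sm.add_constant(
            np.column_stack([cov["age"], cov["sex"], cov["hei"], g])
        )
        gee = sm.GEE(
            y, x, groups=pd.factorize(cov["family_id"])[0],
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Independence(),
        ).fit()
        assert res.beta == pytest.approx(gee.params[-1], abs=1e-6)
        assert res.se == pytest.approx(gee.bse[-1], rel=0.02)

    def test_constant_genotype_flagged(self, caplog):
        y, g, cov = toy_data(seed=3)
        g[:] = 2
        with caplog.at_level("WARNING"):
            res = fit_gee_snp(y, g, cov)
        assert np.isnan(res.p)

    def test_single_cluster_falls_back_to_classical(self, caplog):
        y, g, cov = toy_data(seed=4, families=["f0"] * 80)
        with caplog.at_level("WARNING"):
            res = fit_gee_snp(y, g, cov)
        assert res.se_type == "classical"
        assert np.isfinite(res.p)

    def test_categorical_coding_two_df(self):
        y, g, cov = toy_data(seed=5)
        res = fit_gee_snp(y, g, cov, coding="categorical")
        assert res.coding == "categorical"
        assert 0 <= res.p <= 1

    def test_power_matches_wald_ols_oracle(self):
        """Planted effect beta=0.5, MAF 0.3, n=200: rejection rate of the
        GEE path equals an independently coded Wald-OLS oracle within MC
        error (singleton clusters)."""
        n, beta, reps = 200, 0.5, 120
        rng = np.random.default_rng(42)
        cov = make_covariates(n, seed=0)
        x0 = np.column_stack(
            [np.ones(n), cov["age"], cov["sex"], cov["hei"]]
        )
        hits_pkg = hits_oracle = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n)
            y = beta * g + rng.normal(size=n)
            ys = pd.Series(y, index=cov.index)
            gs = pd.Series(g, index=cov.index, name="rs")
            hits_pkg += fit_gee_snp(ys, gs, cov).p < 0.05
            # oracle: plain OLS t test computed from first principles
            x = np.column_stack([x0, g])
            bhat, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ bhat
            s2 = resid @ resid / (n - x.shape[1])
            se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[-1, -1])
            from scipy import stats as sps

            hits_oracle += 2 * sps.t.sf(abs(bhat[-1] / se), n - x.shape[1]) < 0.05
        assert hits_pkg / reps == pytest.approx(hits_oracle / reps, abs=0.07)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_nan_propagates_and_excluded_from_family(self):
        out = bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.04])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_stepup_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert ((adj >= np.asarray(pvals) - 1e-12) & (adj <= 1 + 1e-12)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in sorted order

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestGenomeScan:
    def test_empty_input_empty_table(self, study):
        out = run_genome_scan(
            pd.Series(1.0, index=study.calls.index),
            study.calls.iloc[:, :0],
            study.covariates,
        )
        assert out.empty

    def test_scan_agrees_with_single_fits(self, met_pc, qc_calls, study):
        sub = qc_calls.iloc[:, :12]
        scan = run_genome_scan(met_pc.pc1, sub, study.covariates)
        for snp in sub.columns[:6]:
            single = fit_gee_snp(met_pc.pc1, sub[snp], study.covariates)
            assert scan.loc[snp, "beta"] == pytest.approx(single.beta, abs=1e-9)
            assert scan.loc[snp, "se"] == pytest.approx(single.se, rel=1e-8)

    def test_invariant_to_snp_and_subject_order(self, met_pc, qc_calls, study, rng):
        sub = qc_calls.iloc[:, :30]
        base = run_genome_scan(met_pc.pc1, sub, study.covariates)
        cols = list(rng.permutation(sub.columns))
        rows = list(rng.permutation(sub.index))
        perm = run_genome_scan(met_pc.pc1, sub.loc[rows, cols], study.covariates)
        pd.testing.assert_frame_equal(
            base.sort_index(), perm.sort_index(), atol=1e-9, rtol=1e-7
        )

    def test_type_one_error_with_sibling_clusters(self):
        """Null phenotype, 1,000 independent SNPs, n=200 with sibling
        clusters: empirical rejection at nominal 0.05 in [0.035, 0.065]."""
        from micronet.simulate import SimConfig, simulate_study

        cfg = SimConfig(n_subjects=200, n_families=130, n_genes=200,
                        within_block_r=0.0, beta_snp=0.0,
                        missing_call_rate=0.0, low_quality_rate=0.0, seed=31)
        s = simulate_study(cfg)
        rng = np.random.default_rng(17)
        pheno = pd.Series(rng.normal(size=200), index=s.calls.index)
        scan = run_genome_scan(pheno, s.calls.iloc[:, :1000], s.covariates)
        rate = (scan["p"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_sandwich_close_to_model_se_iid(self):
        """Homoscedastic singleton-cluster data: sandwich/model-SE ratio in
        [0.8, 1.25] at n=500."""
        n = 500
        rng = np.random.default_rng(9)
        cov = make_covariates(n, seed=1)
        g = pd.DataFrame({"rs": rng.binomial(2, 0.4, n)}, index=cov.index)
        y = pd.Series(rng.normal(size=n), index=cov.index)
        scan = run_genome_scan(y, g, cov)
        x = sm.add_constant(
            np.column_stack([cov["age"], cov["sex"], cov["hei"], g["rs"]])
        )
        model_se = sm.OLS(y, x).fit().bse[-1]
        assert 0.8 <= scan["se"].iloc[0] / model_se <= 1.25

    def test_planted_beta_recovered_without_bias(self):
        """Mean estimate over 60 reps at n=500 within 0.05 SD of the
        generator's effective per-allele effect."""
        from micronet.simulate import (
            SimConfig,
            simulate_genotypes,
            simulate_phenotypes,
        )

        cfg = SimConfig(n_subjects=500, n_families=325, n_genes=40,
                        snps_per_gene=1, ld_block_size=1, within_block_r=0.0,
                        beta_snp=0.6, latent_noise_sd=1.0,
                        missing_call_rate=0.0, low_quality_rate=0.0,
                        causal_module_ids=(1,), n_causal_genes=4, seed=0)
        errs = []
        for rep in range(60):
            import dataclasses

            c = dataclasses.replace(cfg, seed=1000 + rep)
            streams = c.streams()
            calls, _, snp_map, gene_table, meta = simulate_genotypes(
                c, streams=streams)
            gene_models = {g: grp["snp_id"].tolist()
                           for g, grp in snp_map.groupby("gene_id")}
            causal = sorted(gene_models)[:4]
            cov, mets, prots, ann, truth = simulate_phenotypes(
                c, calls, snp_map, gene_models, causal, meta["family_ids"],
                streams=streams)
            pheno = truth["latent"]
            causal_snps = truth["causal_snps"]
            scan = run_genome_scan(pheno, calls[causal_snps], cov)
            errs.append(scan["beta"].mean() - truth["effective_beta"])
        assert abs(np.mean(errs)) < 0.05
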