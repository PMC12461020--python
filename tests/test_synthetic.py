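"""The generator's planted structure must be recoverable by construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omniarch.config import ConfigurationError, SyntheticConfig
from omniarch import synthetic
from omniarch.synthetic import (
    generate_all, generate_annotations, generate_gene_universe,
    generate_interaction_triples, generate_network,
    generate_perturbation_panel, generate_snp_table,
)


class TestGeneUniverse:
    def test_counts_forced_by_config(self):
        cfg = SyntheticConfig(n_genes=100, n_core=10, n_hsp=2,
                              n_perturbagens=50, seed=7)
        genes = generate_gene_universe(cfg)
        assert (genes["consensus_score"] == 11).sum() == 10
        assert genes["is_omim"].sum() >= 1
        assert set(genes.loc[genes["is_omim"], "true_label"]) == {"core"}
        hsp = genes[genes["true_label"] == "hsp"]
        assert len(hsp) == 2 and (hsp["gwas_z"] > 5).all()

    def test_oversized_core_set_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(n_genes=50, n_core=40, n_hsp=20)

    def test_null_expression_shift_gives_comparable_means(self):
        # with no planted shift the standardized core-vs-rest difference is
        # a unit normal; its mean over 10 seeds has SE 1/sqrt(10)
        zs = []
        for seed in range(10):
            cfg = SyntheticConfig(n_genes=2000, n_core=200, n_hsp=10,
                                  n_perturbagens=100, core_expression_shift=0.0,
                                  seed=seed)
            genes = generate_gene_universe(cfg)
            core = genes["true_label"] == "core"
            t = cfg.relevant_tissues[0]
            a, b = genes.loc[core, f"expr_{t}"], genes.loc[~core, f"expr_{t}"]
            se = np.sqrt(a.var() / len(a) + b.var() / len(b))
            zs.append((a.mean() - b.mean()) / se)
        assert abs(np.mean(zs)) <= 2 / np.sqrt(10)

    def test_planted_expression_shift_detected(self):
        # with a 2-SD shift at n=2000, normal theory puts two-sample power
        # at essentially 1 for alpha = 0.001
        cfg = SyntheticConfig(n_genes=2000, n_core=200, n_hsp=10,
                              n_perturbagens=100, core_expression_shift=2.0,
                              seed=11)
        genes = generate_gene_universe(cfg)
        core = genes["true_label"] == "core"
        t = cfg.relevant_tissues[0]
        res = stats.ttest_ind(genes.loc[core, f"expr_{t}"],
                              genes.loc[~core, f"expr_{t}"], equal_var=False)
        assert res.pvalue < 1e-3
        assert res.statistic > 0

    def test_positions_are_bed_compatible(self, small_dataset):
        g = small_dataset.genes
        assert (g["start"] < g["end"]).all()
        assert (g["start"] >= 0).all()
        # gene bodies never overlap on the single synthetic chromosome
        s = g.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_core_genes_have_more_regulatory_elements(self, small_dataset):
        g = small_dataset.genes
        core = g["true_label"] == "core"
        assert g.loc[core, "tss_count"].mean() > g.loc[~core, "tss_count"].mean()


class TestSnpTable:
    def test_row_count_and_pvalue_range(self, small_config, small_dataset):
        snps = small_dataset.snps
        assert len(snps) == small_config.n_snps
        assert ((snps["pvalue"] > 0) & (snps["pvalue"] <= 1)).all()

    def test_every_planted_hsp_is_tagged(self, small_dataset):
        genes, snps = small_dataset.genes, small_dataset.snps
        sig = snps[snps["pvalue"] <= 5e-8]
        for _, g in genes[genes["true_label"] == "hsp"].iterrows():
            d = np.minimum(np.abs(sig["pos"] - g["start"]),
                           np.abs(sig["pos"] - (g["end"] - 1)))
            assert (d < 10_000).any()

    def test_decoys_present_and_flagged(self, small_dataset):
        roles = set(small_dataset.snps["role"])
        assert {"decoy_proximity", "decoy_ld", "hsp_tag", "background"} <= roles
        decoys = small_dataset.snps[small_dataset.snps["role"].str.startswith("decoy")]
        assert (decoys["pvalue"] <= 5e-8).all()


class TestPerturbationPanel:
    def test_zero_fraction_plants_nothing(self, small_dataset):
        cfg = SyntheticConfig(n_genes=100, n_core=10, n_hsp=2, n_perturbagens=50,
                              frac_discriminative=0.0, frac_variance=0.0, seed=3)
        genes = generate_gene_universe(cfg)
        _, truth = generate_perturbation_panel(genes, cfg)
        assert (truth["effect"] == "null").all()

    def test_planted_count_is_deterministic(self):
        cfg = SyntheticConfig(n_genes=300, n_core=30, n_hsp=5, n_perturbagens=100,
                              frac_discriminative=0.3, seed=5)
        genes = generate_gene_universe(cfg)
        _, truth = generate_perturbation_panel(genes, cfg)
        assert (truth["effect"] == "discriminative").sum() == 30

    def test_planted_shift_matches_noncentrality(self):
        # expected |t| of a delta shift on all core genes is about
        # delta / sqrt(1/n_core + 1/n_periph) under unit noise
        cfg = SyntheticConfig(n_genes=2200, n_core=200, n_hsp=10,
                              n_perturbagens=200, frac_discriminative=0.25,
                              frac_variance=0.0, mean_shift_delta=1.0, seed=13)
        genes = generate_gene_universe(cfg)
        panel, truth = generate_perturbation_panel(genes, cfg)
        core = set(genes.loc[genes["true_label"] == "core", "symbol"])
        peri_mask = ~panel.z.columns.isin(core)
        z = panel.z.to_numpy()
        cmask = panel.z.columns.isin(core)
        t_obs = []
        for i in np.flatnonzero((truth["effect"] == "discriminative").to_numpy()):
            res = stats.ttest_ind(z[i, cmask], z[i, peri_mask], equal_var=False)
            t_obs.append(abs(res.statistic))
        n_c, n_p = cmask.sum(), peri_mask.sum()
        expected = 1.0 / np.sqrt(1 / n_c + 1 / n_p)
        assert np.mean(t_obs) == pytest.approx(expected, rel=0.10)

    def test_core_genes_required_among_measured(self):
        cfg = SyntheticConfig(n_genes=100, n_core=10, n_hsp=2, n_perturbagens=50, seed=3)
        genes = generate_gene_universe(cfg)
        genes = genes.assign(true_label="peripheral")
        with pytest.raises(ConfigurationError, match="core"):
            generate_perturbation_panel(genes, cfg)


class TestTriples:
    def test_class_formulas_with_zero_noise(self):
        cfg = SyntheticConfig(n_genes=100, n_core=10, n_hsp=2, n_perturbagens=50,
                              n_triples_per_class=5, triple_noise_sd=0.0,
                              suppression_coeff=0.2, seed=9)
        triples, truth = generate_interaction_triples(cfg)
        from omniarch.interactions import fit_interaction
        for i, cls in enumerate(truth["true_class"]):
            r = fit_interaction(triples[i])
            if cls == "additive":
                assert r.c1 == pytest.approx(1.0, abs=1e-8)
                assert r.c2 == pytest.approx(1.0, abs=1e-8)
            elif cls == "suppression":
                assert r.magnitude == pytest.approx(0.2 * np.sqrt(2), abs=1e-8)

    def test_pure_neomorph_has_no_linear_fit(self):
        cfg = SyntheticConfig(n_genes=100, n_core=10, n_hsp=2, n_perturbagens=50,
                              n_triples_per_class=5, triple_noise_sd=0.0,
                              neomorph_noise_frac=1.0, seed=9)
        triples, truth = generate_interaction_triples(cfg)
        from omniarch.interactions import fit_interaction
        for i, cls in enumerate(truth["true_class"]):
            if cls == "neomorphic":
                assert abs(fit_interaction(triples[i]).model_fit) < 0.05


class TestNetwork:
    def test_ppi_edges_are_doubled(self, small_dataset):
        edges = small_dataset.network
        ppi = edges[edges["edge_type"] == "ppi"]
        fwd = set(zip(ppi["source"], ppi["target"]))
        assert all((b, a) in fwd for a, b in fwd)

    def test_degree_elevation_detected_by_rank_test(self):
        cfg = SyntheticConfig(n_genes=2000, n_core=200, n_hsp=10,
                              n_perturbagens=100, n_edges=6000,
                              degree_elevation=3.0, seed=21)
        genes = generate_gene_universe(cfg)
        edges = generate_network(genes, cfg)
        deg = pd.concat([edges["source"], edges["target"]]).value_counts()
        deg = deg.reindex(genes["symbol"], fill_value=0)
        core = (genes["true_label"] == "core").to_numpy()
        res = stats.mannwhitneyu(deg[core], deg[~core], alternative="greater")
        assert res.pvalue < 0.01

    def test_no_elevation_gives_comparable_degrees(self):
        cfg = SyntheticConfig(n_genes=2000, n_core=200, n_hsp=10,
                              n_perturbagens=100, n_edges=6000,
                              degree_elevation=1.0, seed=21)
        genes = generate_gene_universe(cfg)
        edges = generate_network(genes, cfg)
        deg = pd.concat([edges["source"], edges["target"]]).value_counts()
        deg = deg.reindex(genes["symbol"], fill_value=0).to_numpy(float)
        core = (genes["true_label"] == "core").to_numpy()
        a, b = deg[core], deg[~core]
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) <= 2 * se


class TestAnnotations:
    def test_exact_core_term_is_most_enriched(self, small_dataset, small_classification):
        from omniarch.enrichment import set_enrichment
        universe = set(small_dataset.genes["symbol"])
        res = set_enrichment(set(small_classification.core),
                             small_dataset.annotations, universe)
        best = min(res, key=lambda r: r.pvalue)
        assert best.unit == "T_CORE_EXACT"

    def test_no_empty_terms(self, small_dataset):
        assert all(len(v) > 0 for v in small_dataset.annotations.values())


class TestDeterminism:
    def test_fixed_seed_reproduces_all_layers(self, small_config):
        a, b = generate_all(small_config), generate_all(small_config)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        pd.testing.assert_frame_equal(a.panel.z, b.panel.z)
        np.testing.assert_array_equal(a.triples.AB, b.triples.AB)
        pd.testing.assert_frame_equal(a.network, b.network)

    def test_serialized_bundle_is_byte_identical(self, small_config, tmp_path):
        generate_all(small_config).write(tmp_path / "one")
        generate_all(small_config).write(tmp_path / "two")
        files = sorted(p.name for p in (tmp_path / "one").iterdir())
        assert files
        for name in files:
            assert (tmp_path / "one" / name).read_bytes() == \
                (tmp_path / "two" / name).read_bytes()
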