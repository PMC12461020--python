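"""End-to-end pipeline: simulate -> classify -> hsp -> enrich -> perturb ->
overlap -> interact -> netstats, driven by one config and one master seed.

Every stage records its parameters and key statistics in a JSON report;
tabular outputs are written as TSV next to it.  Re-running with an
identical config reproduces byte-identical outputs (no timestamps are
written)."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import __version__, enrichment, gene_sets, interactions, netstats, perturbation, setops
from ._seeding import stage_rng
from .config import PipelineConfig
from .enrichment import results_frame
from .synthetic import SyntheticDataset, generate_all, generate_perturbation_panel

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute the enabled stages in dependency order; returns the report
    dict (also written to ``<outdir>/report.json``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    report: Dict = {"version": __version__, "config": cfg.to_dict(), "stages": {}}
    stages = set(cfg.stages)

    def need(stage: str, dependency: str, obj) -> None:
        if obj is None:
            raise RuntimeError(f"stage '{stage}' requires stage '{dependency}'")

    dataset: SyntheticDataset | None = None
    classification = None

    if "simulate" in stages:
        syn = cfg.synthetic
        dataset = generate_all(syn)
        dataset.write(out / "data")
        report["stages"]["simulate"] = {
            "n_genes": syn.n_genes, "n_core": syn.n_core, "n_hsp": syn.n_hsp,
            "n_perturbagens": syn.n_perturbagens, "seed": syn.seed,
            "n_edges_written": int(len(dataset.network)),
            "n_snps": int(len(dataset.snps)),
        }

    if "classify" in stages:
        need("classify", "simulate", dataset)
        scores = pd.Series(dataset.genes["consensus_score"].to_numpy(),
                           index=dataset.genes["symbol"])
        omim = set(dataset.genes.loc[dataset.genes["is_omim"], "symbol"])
        classification = gene_sets.classify_genes(scores, omim)
        report["stages"]["classify"] = {
            "n_core": len(classification.core),
            "n_peripheral": len(classification.peripheral),
            "n_excluded": len(classification.excluded),
        }

    if "hsp" in stages:
        need("hsp", "classify", classification)
        z = pd.Series(dataset.genes["gwas_z"].to_numpy(), index=dataset.genes["symbol"])
        hsp_z = gene_sets.select_hsps_by_zscore(classification, z, cfg.hsp_z_threshold)
        hsp_snp = gene_sets.select_hsps_by_snp_proximity(
            dataset.snps, dataset.genes, classification,
            window=cfg.hsp_window, p_cut=cfg.hsp_p_cut)
        classification = classification.with_hsp(hsp_z | hsp_snp)
        planted = set(dataset.genes.loc[dataset.genes["true_label"] == "hsp", "symbol"])
        report["stages"]["hsp"] = {
            "z_threshold": cfg.hsp_z_threshold, "window": cfg.hsp_window,
            "p_cut": cfg.hsp_p_cut,
            "n_hsp_by_z": len(hsp_z), "n_hsp_by_snp": len(hsp_snp),
            "snp_mode_matches_planted": sorted(hsp_snp) == sorted(planted),
        }

    if "enrich" in stages:
        need("enrich", "classify", classification)
        universe = set(dataset.genes["symbol"])
        terms = enrichment.set_enrichment(set(classification.core),
                                          dataset.annotations, universe)
        results_frame(terms).to_csv(out / "term_enrichment.tsv", sep="\t", index=False)
        tissue_rows = []
        classes = {"core": classification.core,
                   "hsp": classification.hsp,
                   "peripheral": classification.peripheral}
        for t in range(cfg.synthetic.n_tissues):
            for cname, cset in classes.items():
                if not cset:
                    continue
                r = enrichment.expression_percentile_odds(
                    dataset.genes, t, cfg.percentile, cset)
                tissue_rows.append({"tissue": f"expr_{t}", "class": cname,
                                    "odds_ratio": r.odds_ratio, "pvalue": r.pvalue})
        tissue_df = pd.DataFrame(tissue_rows)
        tissue_df["fdr"] = enrichment.bh_fdr(tissue_df["pvalue"])
        tissue_df.to_csv(out / "tissue_enrichment.tsv", sep="\t", index=False)
        relevant = [f"expr_{t}" for t in cfg.synthetic.relevant_tissues]
        core_rel = tissue_df[(tissue_df["class"] == "core")
                             & tissue_df["tissue"].isin(relevant)]
        report["stages"]["enrich"] = {
            "n_terms_tested": len(terms),
            "n_terms_fdr05": int(sum(r.fdr < cfg.alpha for r in terms)),
            "core_relevant_tissue_or_min": float(core_rel["odds_ratio"].min()),
        }

    results_a = None
    if "perturb" in stages:
        need("perturb", "classify", classification)
        results_a = perturbation.discriminative_test(
            dataset.panel, classification.core, classification.peripheral,
            alpha=cfg.alpha)
        results_a.frame.to_csv(out / "perturbagens.tsv", sep="\t", index=False,
                               float_format="%.10g")
        by_class = results_a.fraction_by_class({
            "core": classification.core, "peripheral": classification.peripheral,
            "hsp": classification.hsp})
        control = perturbation.random_set_control(
            dataset.panel, dataset.panel.measured_genes,
            set_size=len(classification.core), n_reps=cfg.n_random_controls,
            seed=stage_rng(cfg.seed, "random_set_control"), alpha=cfg.alpha)
        truth_disc = set(dataset.panel_truth.loc[
            dataset.panel_truth["effect"] == "discriminative", "perturbagen"])
        recovered = results_a.significant_perturbagens
        stage = {
            "fraction_significant": results_a.fraction_significant,
            "fraction_variance_significant": results_a.fraction_variance_significant,
            "fraction_by_class": by_class.to_dict(orient="records"),
            "random_control_mean_fraction": float(control.mean()),
            "planted_discriminative_fraction":
                len(truth_disc) / len(dataset.panel.perturbagens),
            "recovered_vs_planted_jaccard":
                len(recovered & truth_disc) / max(1, len(recovered | truth_disc)),
        }
        if len(recovered) >= 2 and len(classification.core) >= 3:
            rc = perturbation.response_correlation(
                dataset.panel, classification.core, recovered)
            stage["response_frac_uncorrelated"] = rc.frac_below
            stage["response_frac_correlated"] = rc.frac_above
        report["stages"]["perturb"] = stage

    if "overlap" in stages:
        need("overlap", "perturb", results_a)
        panel_b, _ = generate_perturbation_panel(
            dataset.genes, cfg.synthetic, cell_line="SYN2", stream="panel_b")
        results_b = perturbation.discriminative_test(
            panel_b, classification.core, classification.peripheral, alpha=cfg.alpha)
        A, B = results_a.significant_perturbagens, results_b.significant_perturbagens
        if A and B:
            table = setops.overlap_table(
                [("SYN1", A, dataset.panel.perturbagens,
                  "SYN2", B, panel_b.perturbagens)],
                n_rand=cfg.n_rand, seed=stage_rng(cfg.seed, "overlap"))
            table.to_csv(out / "overlap.tsv", sep="\t", index=False,
                         float_format="%.10g")
            inull = setops.intersection_null(
                [A, B], [dataset.panel.perturbagens, panel_b.perturbagens],
                set_ids=["SYN1", "SYN2"], n_rand=cfg.n_rand,
                seed=stage_rng(cfg.seed, "intersection_null"))
            report["stages"]["overlap"] = {
                "overlap": float(table["overlap"].iloc[0]),
                "p_empiric": float(table["p_empiric"].iloc[0]),
                "n_rand": cfg.n_rand,
                "n_depleted_patterns": int(inull.depleted.sum()),
            }
        else:
            report["stages"]["overlap"] = {"note": "no significant sets to compare"}

    if "interact" in stages:
        need("interact", "simulate", dataset)
        fits = interactions.fit_triple_set(dataset.triples)
        fits.to_csv(out / "interactions.tsv", sep="\t", index=False,
                    float_format="%.10g")
        stage = {"n_triples": len(fits)}
        for k in cfg.topk:
            if k > len(fits):
                logger.warning("top-k %d exceeds %d fitted triples; skipped",
                               k, len(fits))
                continue
            for rt in interactions.rank_and_test(fits, k=k):
                stage[f"{rt.criterion}_top{k}_chi2_p"] = rt.pvalue
        report["stages"]["interact"] = stage

    if "netstats" in stages:
        need("netstats", "classify", classification)
        net = netstats.MultiModalNetwork(dataset.network)
        cent = netstats.centralities(net)
        cent.to_csv(out / "centralities.tsv", sep="\t", index=False,
                    float_format="%.10g")
        core_mask = cent["symbol"].isin(classification.core)
        peri_mask = cent["symbol"].isin(classification.peripheral)
        stage = {}
        for measure in ("betweenness", "degree", "pagerank"):
            u, p = enrichment.compare_attribute(
                cent.loc[core_mask, measure], cent.loc[peri_mask, measure],
                test="mannwhitney")
            stage[f"{measure}_U"] = u
            stage[f"{measure}_p"] = p
        seeds = set(classification.hsp) & set(net.nodes)
        if seeds:
            scores = netstats.propagate_labels(net, seeds, restart=cfg.restart)
            core_s = scores[scores.index.isin(classification.core)]
            peri_s = scores[scores.index.isin(classification.peripheral - seeds)]
            _, p_rwr = enrichment.compare_attribute(core_s, peri_s, test="mannwhitney")
            stage["rwr_restart"] = cfg.restart
            stage["rwr_core_vs_peripheral_p"] = p_rwr
            stage["rwr_core_mean_minus_peripheral_mean"] = float(
                core_s.mean() - peri_s.mean())
        report["stages"]["netstats"] = stage

    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
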