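"""Synthetic benchmark generator with planted ground truth.

Emulates the input layers of an omnigenic-architecture study on a single
synthetic chromosome: a gene universe with consensus scores and
core/peripheral/HSP labels, tissue expression elevated for core genes in
disease-relevant tissues, a GWAS SNP table with LD blocks and planted
decoys, a perturbagen-by-gene signature panel with planted mean-shift and
variance effects on core genes, perturbation triples (A, B, AB) with
planted additive/suppressive/synergistic/neomorphic structure, a typed
multi-modal network with elevated core-gene degree, and GMT annotation
terms with planted core enrichment.

Ground-truth labels ride along in memory (``true_label`` columns and truth
frames) and are serialized only into the ``truth.tsv`` sidecar, never into
the primary data files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io
from ._seeding import stage_rng
from .config import ConfigurationError, SyntheticConfig
from .interactions import TripleSet
from .perturbation import PerturbationPanel

__all__ = [
    "generate_gene_universe", "generate_snp_table", "generate_perturbation_panel",
    "generate_interaction_triples", "generate_network", "generate_annotations",
    "SyntheticDataset", "generate_all",
    "CLASS_GROUPS",
]

CHROM = "chrS"
CLASS_GROUPS = (
    "core-core", "core-hsp", "core-peripheral",
    "hsp-hsp", "hsp-peripheral", "peripheral-peripheral",
)
TRIPLE_CLASSES = ("additive", "suppression", "synergy", "neomorphic")


def _nbinom(rng: np.random.Generator, mean: float, size: int, r: float = 4.0) -> np.ndarray:
    # negative binomial with dispersion r; p = r / (r + mean)
    return rng.negative_binomial(r, r / (r + mean), size=size)


def generate_gene_universe(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the per-gene table.

    Columns: symbol, consensus_score (core genes 11, an excluded band 1-10,
    rest 0), is_omim (subset of core), gwas_z (HSPs planted with Z > 5),
    chrom/start/end (0-based half-open bodies on one synthetic chromosome),
    tss_count/enhancer_count (negative binomial, higher mean for core),
    expr_<t> per tissue (core genes shifted by ``core_expression_shift`` in
    ``relevant_tissues`` only), and the ground-truth ``true_label`` column
    (core / excluded / peripheral / hsp), which the writer splits into the
    truth sidecar.

    Genome layout: genes with consensus score > 0 occupy every other LD
    block at the chromosome start; peripheral genes follow after a buffer,
    again one gene per two blocks.  The spacing guarantees that a SNP
    planted within the proximity window of one gene is outside the window
    and the LD block of every other scored gene, so the HSP exclusion logic
    is exercised unambiguously.
    """
    config.validate()
    c = config
    rng = stage_rng(c.seed, "gene_universe")

    n_excluded = int(round(c.frac_excluded * c.n_genes))
    if c.n_core + c.n_hsp + n_excluded > c.n_genes:
        raise ConfigurationError("core + hsp + excluded band exceed the universe")

    symbols = np.array([f"G{i:06d}" for i in range(c.n_genes)])
    perm = rng.permutation(c.n_genes)
    core_idx = perm[:c.n_core]
    excl_idx = perm[c.n_core:c.n_core + n_excluded]
    hsp_idx = perm[c.n_core + n_excluded:c.n_core + n_excluded + c.n_hsp]

    label = np.full(c.n_genes, "peripheral", dtype=object)
    label[core_idx] = "core"
    label[excl_idx] = "excluded"
    label[hsp_idx] = "hsp"

    score = np.zeros(c.n_genes, dtype=int)
    score[core_idx] = 11
    score[excl_idx] = rng.integers(1, 11, size=n_excluded)

    is_omim = np.zeros(c.n_genes, dtype=bool)
    n_omim = max(1, int(round(c.frac_omim * c.n_core))) if c.n_core else 0
    if n_omim:
        is_omim[rng.choice(core_idx, size=n_omim, replace=False)] = True

    gwas_z = rng.normal(0.0, 1.0, size=c.n_genes)
    gwas_z[core_idx] = rng.normal(1.0, 1.5, size=c.n_core)
    gwas_z[hsp_idx] = 5.0 + np.abs(rng.normal(0.0, 1.0, size=c.n_hsp))

    # positions: scored genes (CS > 0) first, one per two LD blocks
    B = c.ld_block_size
    start = np.zeros(c.n_genes, dtype=int)
    scored = np.sort(np.concatenate([core_idx, excl_idx]))
    unscored = np.sort(np.setdiff1d(np.arange(c.n_genes), scored))
    start[scored] = 2 * B * np.arange(len(scored))
    offset = 2 * B * len(scored) + 4 * B
    start[unscored] = offset + 2 * B * np.arange(len(unscored))
    end = start + c.gene_length

    tss = np.where(label == "core",
                   _nbinom(rng, c.tss_core_mean, c.n_genes),
                   _nbinom(rng, c.tss_background_mean, c.n_genes))
    enh = np.where(label == "core",
                   _nbinom(rng, c.tss_core_mean, c.n_genes),
                   _nbinom(rng, c.tss_background_mean, c.n_genes))

    genes = pd.DataFrame({
        "symbol": symbols, "consensus_score": score, "is_omim": is_omim,
        "gwas_z": gwas_z, "chrom": CHROM, "start": start, "end": end,
        "tss_count": tss, "enhancer_count": enh, "true_label": label,
    })

    expr = rng.normal(c.expression_base, 1.0, size=(c.n_genes, c.n_tissues))
    for t in c.relevant_tissues:
        expr[core_idx, t] += c.core_expression_shift
    expr = np.clip(expr, 0.0, None)
    for t in range(c.n_tissues):
        genes[f"expr_{t}"] = expr[:, t]
    return genes


def generate_snp_table(genes: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Generate a SNP table (0-based ``pos`` in memory) with planted structure.

    Every ground-truth HSP gene gets a genome-wide-significant SNP 2 kb
    upstream of its body; decoy significant SNPs are planted 3 kb from
    scored (CS > 0) genes and inside the LD block of core/OMIM genes (but
    outside every proximity window), so that both exclusion rules fire.
    Background SNPs fill the table up to ``n_snps`` rows with p-values
    bounded away from genome-wide significance.  The ground-truth ``role``
    column (hsp_tag / decoy_proximity / decoy_ld / background) is sidecar
    material.
    """
    c = config
    rng = stage_rng(c.seed, "snp_table")
    B = c.ld_block_size
    rows: List[dict] = []

    def add(pos: int, pvalue: float, role: str) -> None:
        rows.append({"snp_id": f"rs{len(rows):05d}", "chrom": CHROM,
                     "pos": int(pos), "pvalue": float(pvalue), "role": role})

    hsp = genes[genes["true_label"] == "hsp"]
    for _, g in hsp.iterrows():
        add(g["start"] - 2000, rng.uniform(1e-12, 5e-8), "hsp_tag")

    scored = genes[genes["consensus_score"] > 0]
    for _, g in scored.sample(n=min(c.n_decoy_proximity, len(scored)),
                              random_state=int(rng.integers(2**31))).iterrows():
        add(g["start"] - 3000, rng.uniform(1e-12, 5e-8), "decoy_proximity")

    core = genes[(genes["consensus_score"] == 11) | genes["is_omim"]]
    for _, g in core.sample(n=min(c.n_decoy_ld, len(core)),
                            random_state=int(rng.integers(2**31))).iterrows():
        # same LD block as the core gene, beyond the proximity window of
        # every scored gene body (layout guarantees the neighbours are far)
        add(g["start"] + c.gene_length + c.snp_window + 1,
            rng.uniform(1e-12, 5e-8), "decoy_ld")

    n_background = max(0, c.n_snps - len(rows))
    chrom_len = int(genes["end"].max()) + 2 * B
    for _ in range(n_background):
        add(rng.integers(0, chrom_len), rng.uniform(1e-6, 1.0), "background")

    snps = pd.DataFrame(rows)
    snps["ld_block"] = snps["pos"] // B
    return snps[["snp_id", "chrom", "pos", "pvalue", "ld_block", "role"]]


def generate_perturbation_panel(
    genes: pd.DataFrame, config: SyntheticConfig,
    cell_line: str = "SYN1", perturbation_type: str = "knockdown",
    stream: str = "panel",
) -> Tuple[PerturbationPanel, pd.DataFrame]:
    """Generate a perturbagen-by-gene differential-expression Z panel.

    Baseline entries are iid standard normal (the assumed null of LINCS-style
    consensus Z scores).  A planted fraction ``frac_discriminative`` of
    perturbagens adds ``mean_shift_delta`` with a random per-perturbagen sign
    to every core-gene column; a disjoint fraction ``frac_variance``
    multiplies core-gene entries by ``variance_factor``.  Returns the panel
    and a truth frame (perturbagen, effect, sign).
    """
    c = config
    rng = stage_rng(c.seed, stream)
    core_mask = (genes["true_label"] == "core").to_numpy()
    if not core_mask.any():
        raise ConfigurationError("no core genes among measured genes")

    measured = genes["symbol"].tolist()
    if c.n_perturbagens <= len(measured):
        perturbagens = list(rng.choice(measured, size=c.n_perturbagens, replace=False))
    else:
        raise ConfigurationError("n_perturbagens exceeds the gene universe")

    z = rng.standard_normal((c.n_perturbagens, len(measured)))
    n_disc = int(round(c.frac_discriminative * c.n_perturbagens))
    n_var = int(round(c.frac_variance * c.n_perturbagens))
    special = rng.choice(c.n_perturbagens, size=n_disc + n_var, replace=False)
    disc_rows, var_rows = special[:n_disc], special[n_disc:]

    signs = rng.choice([-1.0, 1.0], size=n_disc)
    z[np.ix_(disc_rows, np.flatnonzero(core_mask))] += signs[:, None] * c.mean_shift_delta
    z[np.ix_(var_rows, np.flatnonzero(core_mask))] *= c.variance_factor

    effect = np.full(c.n_perturbagens, "null", dtype=object)
    effect[disc_rows] = "discriminative"
    effect[var_rows] = "variance"
    sign_col = np.zeros(c.n_perturbagens)
    sign_col[disc_rows] = signs
    truth = pd.DataFrame({"perturbagen": perturbagens, "effect": effect,
                          "sign": sign_col})

    panel = PerturbationPanel(
        cell_line=cell_line, perturbation_type=perturbation_type,
        z=pd.DataFrame(z, index=pd.Index(perturbagens, name="perturbagen"),
                       columns=measured),
    )
    return panel, truth


def generate_interaction_triples(config: SyntheticConfig) -> Tuple[TripleSet, pd.DataFrame]:
    """Generate (A, B, AB) perturbation triples for the four planted classes.

    additive      AB = A + B + eps
    suppression   AB = s (A + B) + eps,   s = suppression_coeff in (0, 1)
    synergy       AB = g (A + B) + eps,   g = synergy_coeff > 1
    neomorphic    AB = (1 - q)(A + B) + q W, W noise orthogonalized against
                  A and B and rescaled to |A + B|, q = neomorph_noise_frac

    Each triple carries an unordered pair-group label; suppression and
    neomorphic triples fall on core-core pairs with probability
    ``class_group_assoc`` (else uniform over groups), emulating planted
    genetic-interaction structure among core genes.
    """
    c = config
    rng = stage_rng(c.seed, "triples")
    d = c.triple_dim
    A_list, B_list, AB_list, pairs, groups, classes = [], [], [], [], [], []

    for cls in TRIPLE_CLASSES:
        for i in range(c.n_triples_per_class):
            A = rng.standard_normal(d)
            B = rng.standard_normal(d)
            eps = rng.normal(0.0, c.triple_noise_sd, size=d)
            if cls == "additive":
                AB = A + B + eps
            elif cls == "suppression":
                AB = c.suppression_coeff * (A + B) + eps
            elif cls == "synergy":
                AB = c.synergy_coeff * (A + B) + eps
            else:  # neomorphic
                W = rng.standard_normal(d)
                # Gram-Schmidt against span(A, B) so W carries no additive part
                B_perp = B - (B @ A) / (A @ A) * A
                for v in (A, B_perp):
                    W = W - (W @ v) / (v @ v) * v
                s = A + B
                W = W / np.linalg.norm(W) * np.linalg.norm(s)
                AB = (1.0 - c.neomorph_noise_frac) * s + c.neomorph_noise_frac * W
            if cls in ("suppression", "neomorphic") and rng.random() < c.class_group_assoc:
                grp = "core-core"
            else:
                grp = CLASS_GROUPS[rng.integers(len(CLASS_GROUPS))]
            n = len(pairs)
            A_list.append(A); B_list.append(B); AB_list.append(AB)
            pairs.append((f"PA{n:04d}", f"PB{n:04d}"))
            groups.append(grp)
            classes.append(cls)

    triples = TripleSet(A=np.array(A_list), B=np.array(B_list), AB=np.array(AB_list),
                        pairs=pairs, groups=groups)
    truth = pd.DataFrame({
        "pair": [f"{a}|{b}" for a, b in pairs],
        "group": groups, "true_class": classes,
    })
    return triples, truth


def generate_network(genes: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Generate a typed directed edge list over gene symbols.

    Endpoints are drawn with probability proportional to a weight that is
    ``degree_elevation`` for core genes and 1 otherwise, giving core genes
    elevated expected degree.  PPI edges are emitted as two directed edges
    running in opposite directions; regulatory edges carry a tissue tag.
    """
    c = config
    rng = stage_rng(c.seed, "network")
    symbols = genes["symbol"].to_numpy()
    w = np.where((genes["true_label"] == "core").to_numpy(), c.degree_elevation, 1.0)
    p = w / w.sum()
    tissues = [f"tissue_{t}" for t in range(c.n_tissues)]

    rows = []
    for _ in range(c.n_edges):
        u, v = rng.choice(len(symbols), size=2, replace=False, p=p)
        r = rng.random()
        if r < 0.5:
            rows.append((symbols[u], symbols[v], "ppi", "-"))
            rows.append((symbols[v], symbols[u], "ppi", "-"))
        elif r < 0.9:
            rows.append((symbols[u], symbols[v], "regulatory",
                         tissues[rng.integers(c.n_tissues)]))
        else:
            rows.append((symbols[u], symbols[v], "metabolic", "-"))
    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type", "tissue"])
    return edges.drop_duplicates(ignore_index=True)


def generate_annotations(
    genes: pd.DataFrame, config: SyntheticConfig,
) -> Tuple[Dict[str, Set[str]], pd.DataFrame]:
    """Generate GMT-style annotation terms with planted core enrichment.

    ``n_enriched_terms`` terms sample members with 10x weight on core genes;
    optionally one term equals the core set exactly; the remainder are
    uniform random draws.  Empty terms are never emitted.
    """
    c = config
    rng = stage_rng(c.seed, "annotations")
    symbols = genes["symbol"].to_numpy()
    core = genes.loc[genes["true_label"] == "core", "symbol"].to_numpy()
    w_enriched = np.where(np.isin(symbols, core), 10.0, 1.0)
    w_enriched /= w_enriched.sum()

    terms: Dict[str, Set[str]] = {}
    enriched_flags = {}
    if c.include_exact_core_term and len(core):
        terms["T_CORE_EXACT"] = set(core)
        enriched_flags["T_CORE_EXACT"] = True
    for i in range(c.n_terms):
        size = int(rng.integers(10, min(101, len(symbols))))
        if i < c.n_enriched_terms:
            members = rng.choice(symbols, size=size, replace=False, p=w_enriched)
            name = f"T_ENRICHED_{i:03d}"
            enriched_flags[name] = True
        else:
            members = rng.choice(symbols, size=size, replace=False)
            name = f"T_RANDOM_{i:03d}"
            enriched_flags[name] = False
        if len(members):
            terms[name] = set(members)
    truth = pd.DataFrame({"term": list(enriched_flags),
                          "enriched": list(enriched_flags.values())})
    return terms, truth


@dataclass
class SyntheticDataset:
    """The full bundle of generated inputs plus their ground truth."""

    config: SyntheticConfig
    genes: pd.DataFrame
    snps: pd.DataFrame
    panel: PerturbationPanel
    panel_truth: pd.DataFrame
    triples: TripleSet
    triple_truth: pd.DataFrame
    network: pd.DataFrame
    annotations: Dict[str, Set[str]] = field(default_factory=dict)
    annotation_truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def truth_frame(self) -> pd.DataFrame:
        """Long-format ground truth across all generated layers."""
        parts = [
            pd.DataFrame({"kind": "gene", "id": self.genes["symbol"],
                          "label": self.genes["true_label"]}),
            pd.DataFrame({"kind": "snp", "id": self.snps["snp_id"],
                          "label": self.snps["role"]}),
            pd.DataFrame({"kind": "perturbagen", "id": self.panel_truth["perturbagen"],
                          "label": self.panel_truth["effect"]}),
            pd.DataFrame({"kind": "triple", "id": self.triple_truth["pair"],
                          "label": self.triple_truth["true_class"]}),
        ]
        if len(self.annotation_truth):
            parts.append(pd.DataFrame({
                "kind": "term", "id": self.annotation_truth["term"],
                "label": self.annotation_truth["enriched"].map(
                    {True: "enriched", False: "random"}),
            }))
        return pd.concat(parts, ignore_index=True)

    def write(self, outdir) -> None:
        """Serialize the bundle; ground truth goes only to truth.tsv."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gcols = ["symbol", "consensus_score", "is_omim", "gwas_z",
                 "chrom", "start", "end", "tss_count", "enhancer_count"]
        self.genes[gcols].to_csv(out / "genes.tsv", sep="\t", index=False,
                                 float_format=io.FLOAT_FMT)
        expr_cols = [c for c in self.genes.columns if c.startswith("expr_")]
        self.genes[["symbol", *expr_cols]].to_csv(
            out / "expression.tsv", sep="\t", index=False, float_format=io.FLOAT_FMT)
        io.write_bed(self.genes, out / "genes.bed")
        io.write_snp_table(self.snps, out / "snps.tsv")
        io.write_panel_matrix(self.panel.z, out / "panel.tsv")
        with open(out / "panel.meta.yaml", "w") as fh:
            yaml.safe_dump({"cell_line": self.panel.cell_line,
                            "perturbation_type": self.panel.perturbation_type}, fh)
        self.triples.to_npz(out / "triples.npz")
        io.write_network(self.network, out / "network.tsv")
        io.write_gmt(self.annotations, out / "annotations.gmt")
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)


def generate_all(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every input layer from one config (one master seed)."""
    genes = generate_gene_universe(config)
    snps = generate_snp_table(genes, config)
    panel, panel_truth = generate_perturbation_panel(genes, config)
    triples, triple_truth = generate_interaction_triples(config)
    network = generate_network(genes, config)
    annotations, annotation_truth = generate_annotations(genes, config)
    return SyntheticDataset(
        config=config, genes=genes, snps=snps,
        panel=panel, panel_truth=panel_truth,
        triples=triples, triple_truth=triple_truth,
        network=network, annotations=annotations,
        annotation_truth=annotation_truth,
    )
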