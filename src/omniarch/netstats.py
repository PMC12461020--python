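"""Network-level statistics over the multi-modal gene network.

The network is a typed directed multigraph (undirected PPIs stored as two
directed edges running in opposite directions).  Centralities are computed
on the simple directed graph obtained by collapsing parallel typed edges;
label propagation is random walk with restart (personalized PageRank);
attribution scores from an interpretable-model ensemble are min-max scaled
per model, averaged across the ensemble and max-aggregated across core
genes; the edge-type composition of high-importance subnetworks is tested
with exact binomial statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .enrichment import bh_fdr

__all__ = [
    "MultiModalNetwork", "centralities", "propagate_labels",
    "aggregate_attributions", "edge_composition",
]

logger = logging.getLogger(__name__)


@dataclass
class MultiModalNetwork:
    """Typed directed multigraph over gene symbols.

    Built from an edge list (source, target, edge_type, tissue); PPI input
    rows are assumed already doubled (one row per direction), as produced
    by the synthetic generator and standard edge exports.
    """

    edges: pd.DataFrame
    nodes: List[str] = field(default_factory=list)

    def __post_init__(self):
        required = {"source", "target", "edge_type"}
        if not required <= set(self.edges.columns):
            raise ValueError(f"edge list needs columns {sorted(required)}")
        if "tissue" not in self.edges.columns:
            self.edges = self.edges.assign(tissue="-")
        endpoint_nodes = set(self.edges["source"]) | set(self.edges["target"])
        if not self.nodes:
            self.nodes = sorted(endpoint_nodes)
        elif not endpoint_nodes <= set(self.nodes):
            raise ValueError("edge endpoints outside the declared node set")

    @property
    def edge_types(self) -> Set[str]:
        return set(self.edges["edge_type"])

    def multigraph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, edge_type=row.edge_type,
                       tissue=row.tissue)
        return g

    def collapsed(self) -> nx.DiGraph:
        """Simple directed graph with parallel typed edges collapsed."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            self.edges[["source", "target"]].drop_duplicates().itertuples(index=False))
        return g


def centralities(net: MultiModalNetwork) -> pd.DataFrame:
    """Per-node betweenness (normalized), degree (in + out on the collapsed
    graph) and PageRank (damping 0.85)."""
    g = net.collapsed()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    btw = nx.betweenness_centrality(g, normalized=True)
    pr = nx.pagerank(g, alpha=0.85)
    deg = dict(g.degree())
    return pd.DataFrame({
        "symbol": list(g.nodes),
        "betweenness": [btw[n] for n in g.nodes],
        "degree": [deg[n] for n in g.nodes],
        "pagerank": [pr[n] for n in g.nodes],
    })


def propagate_labels(
    net: MultiModalNetwork,
    seeds: Iterable[str],
    restart: float = 0.15,
) -> pd.Series:
    """Random-walk-with-restart stationary scores from a seed set.

    Implemented as personalized PageRank with damping 1 - restart and
    uniform restart mass on the seeds; scores sum to 1.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    if not 0 < restart < 1:
        raise ValueError("restart must lie in (0, 1)")
    g = net.collapsed()
    missing = seeds - set(g.nodes)
    if missing:
        raise ValueError(f"seeds outside the network: {sorted(missing)[:5]}")
    personalization = {n: (1.0 / len(seeds) if n in seeds else 0.0) for n in g.nodes}
    scores = nx.pagerank(g, alpha=1.0 - restart, personalization=personalization)
    return pd.Series(scores, name="rwr_score")


def aggregate_attributions(
    per_model_scores: np.ndarray,
    mode: str = "edge",
) -> np.ndarray:
    """Aggregate per-model attribution scores across an ensemble.

    ``per_model_scores`` has shape (n_models, n_items) or, with a per-core-
    gene axis, (n_models, n_items, n_core_genes).  Per model (and core
    gene): ``mode="input"`` min-max scales signed scores to [-1, 1];
    ``mode="edge"`` min-max scales absolute values to [0, 1].  Scores are
    then averaged across models and, if the core-gene axis is present, the
    final per-item score is the maximum across core genes.  A constant
    score vector scales to 0 with a warning.
    """
    x = np.asarray(per_model_scores, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    elif x.ndim != 3:
        raise ValueError("expected a (models, items[, core genes]) array")
    if x.shape[0] < 1:
        raise ValueError("need at least one model")

    if mode == "edge":
        x = np.abs(x)
    elif mode != "input":
        raise ValueError(f"unknown mode {mode!r}")

    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn("constant attribution vector(s) scaled to 0")
    span = np.where(degenerate, 1.0, span)
    unit = (x - lo) / span                       # [0, 1]
    scaled = 2.0 * unit - 1.0 if mode == "input" else unit
    scaled = np.where(np.broadcast_to(degenerate, scaled.shape), 0.0, scaled)
    return scaled.mean(axis=0).max(axis=-1)


def edge_composition(
    edges: pd.DataFrame,
    threshold: float = 0.75,
    trait_col: str | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Edge-type composition of the high-importance subnetwork.

    Among edges with ``importance >= threshold``: relative frequency per
    edge type (per trait if ``trait_col`` names a trait column), an exact
    Clopper-Pearson CI around the expected frequency (the pooled frequency
    across traits), and a two-sided exact binomial test of each trait's
    count against the pooled expectation, BH-adjusted.  With a single
    trait the expectation equals the observation and all p-values are 1.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if "importance" not in edges.columns:
        raise ValueError("edges need an 'importance' column")
    high = edges[edges["importance"] >= threshold].copy()
    if high.empty:
        raise ValueError("no edges above the importance threshold")
    if trait_col is None:
        trait_col = "_trait"
        high[trait_col] = "all"

    pooled = high["edge_type"].value_counts(normalize=True)
    rows = []
    for trait, sub in high.groupby(trait_col):
        n = len(sub)
        counts = sub["edge_type"].value_counts()
        for etype in pooled.index:
            k = int(counts.get(etype, 0))
            exp_p = float(pooled[etype])
            lo, hi = proportion_confint(round(exp_p * n), n, alpha=1 - ci,
                                        method="beta")
            p = stats.binomtest(k, n, exp_p, alternative="two-sided").pvalue
            rows.append({"trait": trait, "edge_type": etype, "n_high": n,
                         "count": k, "frequency": k / n, "expected": exp_p,
                         "ci_lower": float(lo), "ci_upper": float(hi),
                         "pvalue": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pvalue"])
    return out
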