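"""Core/peripheral/excluded classification and HSP selection.

Core genes are the union of the consensus-score-11 predictions and the
OMIM-derived training genes; peripheral genes have consensus score 0 (minus
OMIM genes); genes scoring 1-10 are excluded from downstream contrasts.
Highly significant peripheral genes (HSPs) are selected either by
gene-level GWAS Z score (strictly greater than a threshold, default 5) or
by proximity (< 10 kb) to genome-wide-significant SNPs that survive
exclusion rules guarding against genetic correlates of scored genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import numpy as np
import pandas as pd

__all__ = ["Classification", "classify_genes", "select_hsps_by_zscore",
           "select_hsps_by_snp_proximity", "snp_gene_distance"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Classification:
    """Disjoint partition of the gene universe, plus the HSP subset."""

    core: frozenset
    peripheral: frozenset
    excluded: frozenset
    hsp: frozenset = frozenset()

    def __post_init__(self):
        assert not (self.core & self.peripheral)
        assert not (self.core & self.excluded)
        assert not (self.peripheral & self.excluded)
        assert self.hsp <= self.peripheral

    @property
    def universe(self) -> frozenset:
        return self.core | self.peripheral | self.excluded

    def with_hsp(self, hsp: Iterable) -> "Classification":
        return Classification(self.core, self.peripheral, self.excluded,
                              frozenset(hsp) & self.peripheral)


def classify_genes(cs_table: Mapping[str, int], omim_genes: Iterable[str]) -> Classification:
    """Partition genes by consensus score with OMIM precedence.

    core = {CS = 11} ∪ OMIM; peripheral = {CS = 0} \\ OMIM;
    excluded = {CS in 1..10} \\ OMIM.  OMIM genes missing from the score
    table are appended to the universe with a warning (they are training
    labels and carry no score).
    """
    if isinstance(cs_table, pd.Series):
        cs_table = cs_table.to_dict()
    omim = set(omim_genes)
    bad = {g: s for g, s in cs_table.items()
           if not (isinstance(s, (int, np.integer)) and 0 <= s <= 11)}
    if bad:
        raise ValueError(f"consensus scores outside 0..11: {bad}")
    missing = omim - set(cs_table)
    if missing:
        logger.warning("OMIM genes absent from score table, appended to universe: %s",
                       sorted(missing))
    core = {g for g, s in cs_table.items() if s == 11} | omim
    peripheral = {g for g, s in cs_table.items() if s == 0} - omim
    excluded = {g for g, s in cs_table.items() if 1 <= s <= 10} - omim
    return Classification(frozenset(core), frozenset(peripheral), frozenset(excluded))


def select_hsps_by_zscore(
    classification: Classification,
    gwas_z: Mapping[str, float],
    threshold: float = 5.0,
) -> Set[str]:
    """Peripheral genes with gene-level GWAS Z strictly above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(gwas_z, pd.Series):
        gwas_z = gwas_z.to_dict()
    hsps = set()
    for g in classification.peripheral:
        if g not in gwas_z or pd.isna(gwas_z[g]):
            logger.warning("no GWAS Z score for peripheral gene %s; skipped", g)
            continue
        if gwas_z[g] > threshold:
            hsps.add(g)
    return hsps


def snp_gene_distance(pos: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Base-pair distance from SNP positions to gene bodies (0-based
    half-open): 0 inside the body, else distance to the nearest body edge.
    Strand-agnostic by construction.  Broadcasts to (n_snps, n_genes)."""
    pos = np.asarray(pos)[:, None]
    before = start[None, :] - pos          # > 0 when SNP upstream of body
    after = pos - (end[None, :] - 1)       # > 0 when SNP downstream of body
    return np.maximum(np.maximum(before, after), 0)


def select_hsps_by_snp_proximity(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    classification: Classification,
    window: int = 10_000,
    p_cut: float = 5e-8,
    apply_proximity_exclusion: bool = True,
    apply_ld_exclusion: bool = True,
) -> Set[str]:
    """Peripheral genes within ``window`` bp of surviving significant SNPs.

    Steps: (1) keep SNPs with p <= ``p_cut``; (2) discard kept SNPs whose
    distance to the body of any gene with consensus score > 0 is strictly
    below ``window``, or whose LD block contains an OMIM gene or a
    score-11 core gene; (3) return peripheral genes whose body lies
    strictly within ``window`` of a surviving SNP.  "Less than window" is a
    strict inequality; "p_cut or lower" is <=.  The exclusion toggles exist
    for calibration/property checks only.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    genes = genes.copy()
    has_coords = genes[["start", "end"]].notna().all(axis=1)
    if not has_coords.all():
        logger.warning("%d genes lack coordinates; excluded from distance computation",
                       (~has_coords).sum())
        genes = genes[has_coords]

    sig = snps[snps["pvalue"] <= p_cut]
    if sig.empty:
        return set()

    start = genes["start"].to_numpy(int)
    end = genes["end"].to_numpy(int)
    dist = snp_gene_distance(sig["pos"].to_numpy(int), start, end)
    same_chrom = (sig["chrom"].to_numpy()[:, None] == genes["chrom"].to_numpy()[None, :])
    dist = np.where(same_chrom, dist, np.iinfo(np.int64).max)

    keep = np.ones(len(sig), dtype=bool)
    if apply_proximity_exclusion:
        scored = (genes["consensus_score"].to_numpy() > 0)
        keep &= ~(dist[:, scored] < window).any(axis=1)
    if apply_ld_exclusion and "ld_block" in sig.columns:
        # LD blocks occupied by OMIM genes or score-11 core genes
        protected = genes["is_omim"].to_numpy(bool) | (genes["consensus_score"].to_numpy() == 11)
        blocked = _gene_blocks(genes[protected], snps)
        keep &= ~sig["ld_block"].isin(blocked).to_numpy()

    surviving = sig[keep]
    if surviving.empty:
        return set()

    periph_mask = genes["symbol"].isin(classification.peripheral).to_numpy()
    dist_p = snp_gene_distance(surviving["pos"].to_numpy(int),
                               start[periph_mask], end[periph_mask])
    same = (surviving["chrom"].to_numpy()[:, None]
            == genes.loc[periph_mask, "chrom"].to_numpy()[None, :])
    near = (dist_p < window) & same
    hits = near.any(axis=0)
    return set(genes.loc[periph_mask, "symbol"].to_numpy()[hits])


def _gene_blocks(genes: pd.DataFrame, snps: pd.DataFrame) -> Set[int]:
    """LD blocks overlapped by the given gene bodies.

    Blocks are fixed-width non-overlapping intervals identified by
    ``pos // width``; the width is recovered from the SNP table's
    position -> block mapping (block b constrains pos/(b+1) < width <=
    pos/b), which is exact whenever a consistent fixed width exists.
    """
    if genes.empty or snps.empty:
        return set()
    pos = snps["pos"].to_numpy(int)
    blk = snps["ld_block"].to_numpy(int)
    nz = blk > 0
    if not nz.any():
        return set()
    hi = int(np.min(pos[nz] // blk[nz]))
    lo = int(np.max(pos[nz] // (blk[nz] + 1))) + 1
    width = next((w for w in range(hi, lo - 1, -1)
                  if w > 0 and np.all(pos // w == blk)), 0)
    if width <= 0:
        logger.warning("could not recover a consistent LD-block width; "
                       "LD exclusion skipped")
        return set()
    blocks: Set[int] = set()
    for s, e in zip(genes["start"].to_numpy(int), genes["end"].to_numpy(int)):
        blocks.update(range(s // width, (e - 1) // width + 1))
    return blocks
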