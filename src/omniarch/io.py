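"""Readers and writers for the plain-text formats used throughout.

Conventions
-----------
* Gene coordinates are stored 0-based half-open internally (BED convention).
  SNP tables on disk carry 1-based positions; :func:`read_snp_table` converts
  to 0-based at the boundary and :func:`write_snp_table` converts back.
* Ground-truth labels of synthetic data live in a sidecar ``truth.tsv`` and
  are never embedded in the primary data files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Set

import pandas as pd

__all__ = [
    "read_gene_scores", "read_gene_list", "write_gene_list",
    "read_bed", "write_bed",
    "read_snp_table", "write_snp_table",
    "read_panel_matrix", "write_panel_matrix",
    "read_gmt", "write_gmt",
    "read_network", "write_network",
]

FLOAT_FMT = "%.10g"  # documented float formatting for byte-stable output


def read_gene_scores(path) -> pd.Series:
    """Read a two-column TSV (gene, consensus_score) into a Series."""
    df = pd.read_csv(path, sep="\t")
    gene_col, score_col = df.columns[:2]
    return pd.Series(df[score_col].to_numpy(), index=df[gene_col], name="consensus_score")


def read_gene_list(path) -> List[str]:
    """Read one gene symbol per line, ignoring blanks and '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (chrom, start, end, name) with 0-based half-open coords."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "symbol"])
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "symbol"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP TSV (snp_id, chrom, pos, pvalue, ld_block); pos is 1-based
    on disk and converted to 0-based here."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_snp_table(snps: pd.DataFrame, path) -> None:
    out = snps[["snp_id", "chrom", "pos", "pvalue", "ld_block"]].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_panel_matrix(path) -> pd.DataFrame:
    """Read a signature matrix TSV: header row of measured genes, first
    column of perturbagen identifiers."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_panel_matrix(z: pd.DataFrame, path) -> None:
    z.to_csv(path, sep="\t", index_label="perturbagen", float_format=FLOAT_FMT)


def read_gmt(path) -> Dict[str, Set[str]]:
    """Read GMT gene sets: term <tab> description <tab> gene1 <tab> ..."""
    terms: Dict[str, Set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        name, genes = fields[0], {g for g in fields[2:] if g}
        if genes:
            terms[name] = genes
    return terms


def write_gmt(terms: Dict[str, Set[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(terms):
            genes = sorted(terms[name])
            if not genes:  # degenerate empty terms are dropped
                continue
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_network(path) -> pd.DataFrame:
    """Read a typed edge list TSV (source, target, edge_type, tissue[, importance])."""
    return pd.read_csv(path, sep="\t")


def write_network(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
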