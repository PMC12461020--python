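"""Enrichment and group-comparison statistics.

Validation statistics for gene-class analyses: odds ratios of gene classes
among the most strongly expressed genes per tissue (Fisher's exact test),
hypergeometric enrichment of annotation terms in the core set,
Fisher-exact validation enrichment of candidate bins against peripheral
genes, and generic two-sample attribute comparisons (Welch t,
Mann-Whitney U).  Every "FDR" is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult", "odds_ratio", "bh_fdr",
    "expression_percentile_odds", "set_enrichment",
    "validation_enrichment", "compare_attribute",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test: unit label, counts (a, b, c, d), sample
    odds ratio, p-value and (once adjusted across the family) BH FDR."""

    unit: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    pvalue: float
    fdr: float = np.nan

    def counts(self) -> Tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc with the Haldane-Anscombe +0.5 correction
    applied to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _attach_fdr(results: List[EnrichmentResult]) -> List[EnrichmentResult]:
    fdrs = bh_fdr([r.pvalue for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def expression_percentile_odds(
    genes: pd.DataFrame,
    tissue,
    percentile: float,
    class_set: Iterable[str],
    background: Iterable[str] | None = None,
) -> EnrichmentResult:
    """Odds ratio of ``class_set`` being among the top ``percentile``
    fraction of genes ranked by expression in ``tissue`` (descending,
    average ranks for ties), with a two-sided Fisher exact p.

    ``tissue`` may be a column name or a tissue index (column ``expr_<i>``).
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    col = tissue if isinstance(tissue, str) else f"expr_{int(tissue)}"
    if col not in genes.columns:
        raise KeyError(f"no expression column {col!r}")
    df = genes[["symbol", col]]
    if background is not None:
        df = df[df["symbol"].isin(set(background))]
    class_set = set(class_set) & set(df["symbol"])
    if not class_set:
        raise ValueError("class set is empty within the background")

    ranks = stats.rankdata(-df[col].to_numpy(), method="average")
    top_mask = ranks <= percentile * len(df)
    if not top_mask.any():
        raise ValueError("empty top set at this percentile")
    in_class = df["symbol"].isin(class_set).to_numpy()
    a = int((in_class & top_mask).sum())
    b = int((in_class & ~top_mask).sum())
    c = int((~in_class & top_mask).sum())
    d = int((~in_class & ~top_mask).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(unit=str(col), a=a, b=b, c=c, d=d,
                            odds_ratio=odds_ratio(a, b, c, d), pvalue=float(p))


def set_enrichment(
    target: Set[str],
    terms: Mapping[str, Set[str]],
    universe: Set[str],
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in ``target``.

    Terms are intersected with the universe; p = P[X >= overlap] with
    X ~ Hypergeom(|U|, |term|, |target|); BH FDR across terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not set(target) <= universe:
        raise ValueError("target must be a subset of the universe")
    target = set(target)
    M, N = len(universe), len(target)
    results = []
    for name, members in terms.items():
        term = set(members) & universe
        if not term:
            continue
        n = len(term)
        k = len(term & target)
        p = stats.hypergeom.sf(k - 1, M, n, N)
        a, b, c, d = k, N - k, n - k, M - n - N + k
        results.append(EnrichmentResult(unit=name, a=a, b=b, c=c, d=d,
                                        odds_ratio=odds_ratio(a, b, c, d),
                                        pvalue=float(p)))
    return _attach_fdr(results)


def validation_enrichment(
    bins: Mapping[str, Set[str]],
    reference: Set[str],
    peripheral: Set[str],
) -> List[EnrichmentResult]:
    """Fisher-exact enrichment of reference membership in each candidate
    bin against the peripheral genes; BH FDR across bins.  Empty bins are
    skipped with a warning."""
    reference = set(reference)
    peripheral = set(peripheral)
    c = len(peripheral & reference)
    d = len(peripheral - reference)
    results = []
    for name, members in bins.items():
        members = set(members)
        if not members:
            logger.warning("empty bin %s skipped", name)
            continue
        if members & peripheral:
            raise ValueError(f"bin {name} overlaps the peripheral set")
        a = len(members & reference)
        b = len(members - reference)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(unit=name, a=a, b=b, c=c, d=d,
                                        odds_ratio=odds_ratio(a, b, c, d),
                                        pvalue=float(p)))
    return _attach_fdr(results)


def compare_attribute(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "welch_t",
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Two-sample comparison of a per-gene attribute.

    ``test`` is ``"welch_t"`` (unequal-variance t) or ``"mannwhitney"``
    (the U statistic is reported for the first sample).  Two identical
    constant samples under the t test return (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if test == "welch_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def results_frame(results: List[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (unit, a, b, c, d, odds_ratio, pvalue, fdr)."""
    return pd.DataFrame([{
        "unit": r.unit, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
        "odds_ratio": r.odds_ratio, "pvalue": r.pvalue, "fdr": r.fdr,
    } for r in results])
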