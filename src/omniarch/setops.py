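"""Overlap coefficient with resampling empirical p-values, and empirical
nulls for multi-set (UpSet-style) intersections.

The overlap coefficient Overlap(A, B) = |A ∩ B| / min(|A|, |B|) compares
sets drawn from different universes (e.g. discriminative perturbagens
tested in two cell types).  Its significance is assessed against a null of
size-matched random sets: the observed coefficient's rank r among n_rand
null coefficients is transformed into a two-sided empirical p-value via
r' = r / (n_rand + 1), p = min(r', 1 - r') * 2, so p can never be exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .enrichment import bh_fdr

__all__ = [
    "overlap_coefficient", "empirical_rank_pvalue", "empirical_overlap_pvalue",
    "OverlapResult", "overlap_table", "intersection_null",
    "IntersectionNullResult",
]


def overlap_coefficient(A: Set, B: Set) -> float:
    """|A ∩ B| / min(|A|, |B|); both sets must be non-empty."""
    if not A or not B:
        raise ValueError("overlap coefficient requires non-empty sets")
    return len(set(A) & set(B)) / min(len(A), len(B))


def empirical_rank_pvalue(r: int, n_null: int) -> float:
    """Two-sided empirical p from a rank r in [1, n_null]:
    r' = r/(n_null + 1), p = min(r', 1 - r') * 2."""
    if not 1 <= r <= n_null:
        raise ValueError("rank must lie in [1, n_null]")
    r_prime = r / (n_null + 1)
    return min(r_prime, 1 - r_prime) * 2


@dataclass
class OverlapResult:
    """Observed overlap with its empirical rank-based p-value."""

    set_a_id: str
    set_b_id: str
    overlap: float
    r_empiric: int
    p_empiric: float
    n_rand: int
    fdr: float = np.nan


def _random_membership(rng: np.random.Generator, n_rand: int,
                       universe_size: int, set_size: int) -> np.ndarray:
    """Boolean (n_rand, universe_size) matrix of size-matched random sets."""
    u = rng.random((n_rand, universe_size))
    idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
    mask = np.zeros((n_rand, universe_size), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    return mask


def empirical_overlap_pvalue(
    A: Set, B: Set,
    universe_a: Sequence, universe_b: Sequence,
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
    pairing: str = "paired",
    set_a_id: str = "A", set_b_id: str = "B",
) -> OverlapResult:
    """Empirical two-sided p-value of the overlap coefficient.

    Draws ``n_rand`` random sets matched in size to A from universe_a and
    likewise for B; with ``pairing="paired"`` (default) the draws are
    paired index-wise into n_rand null coefficients, with ``"cross"`` all
    n_rand² cross pairs are used.  The rank convention r = 1 + #{null <
    observed} (clamped to [1, n_rand]) prevents p = 0; the transformation
    is r' = r/(n_rand + 1), p = min(r', 1 - r') * 2.
    """
    universe_a, universe_b = list(universe_a), list(universe_b)
    if not set(A) <= set(universe_a):
        raise ValueError("A is not contained in universe_a")
    if not set(B) <= set(universe_b):
        raise ValueError("B is not contained in universe_b")
    observed = overlap_coefficient(A, B)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # membership over the union so intersections can be counted by matmul
    union = sorted(set(universe_a) | set(universe_b))
    pos = {g: i for i, g in enumerate(union)}
    cols_a = np.array([pos[g] for g in universe_a])
    cols_b = np.array([pos[g] for g in universe_b])

    mask_a = np.zeros((n_rand, len(union)), dtype=bool)
    mask_a[:, cols_a] = _random_membership(rng, n_rand, len(universe_a), len(A))
    mask_b = np.zeros((n_rand, len(union)), dtype=bool)
    mask_b[:, cols_b] = _random_membership(rng, n_rand, len(universe_b), len(B))

    denom = min(len(A), len(B))
    if pairing == "paired":
        inter = (mask_a & mask_b).sum(axis=1)
        null = inter / denom
    elif pairing == "cross":
        inter = mask_a.astype(np.int32) @ mask_b.astype(np.int32).T
        null = (inter / denom).ravel()
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    n_null = null.size
    r = 1 + int((null < observed).sum())
    r = min(max(r, 1), n_null)
    p = empirical_rank_pvalue(r, n_null)
    return OverlapResult(set_a_id=set_a_id, set_b_id=set_b_id, overlap=observed,
                         r_empiric=r, p_empiric=float(p), n_rand=n_null)


def overlap_table(
    pairs: Sequence[Tuple[str, Set, Sequence, str, Set, Sequence]],
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
    pairing: str = "paired",
) -> pd.DataFrame:
    """Empirical overlap p-values for many (set, universe) pairs with one
    BH-FDR family across all requested pairs.

    Each element of ``pairs`` is (id_a, A, universe_a, id_b, B, universe_b).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = [
        empirical_overlap_pvalue(A, B, ua, ub, n_rand=n_rand, seed=rng,
                                 pairing=pairing, set_a_id=ida, set_b_id=idb)
        for ida, A, ua, idb, B, ub in pairs
    ]
    fdrs = bh_fdr([r.p_empiric for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return pd.DataFrame([{
        "set_a": r.set_a_id, "set_b": r.set_b_id, "overlap": r.overlap,
        "r_empiric": r.r_empiric, "p_empiric": r.p_empiric, "fdr": r.fdr,
    } for r in results])


@dataclass
class IntersectionNullResult:
    """Observed exclusive-intersection sizes against a size-matched
    empirical null (per UpSet-style pattern)."""

    patterns: List[Tuple[str, ...]]
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    depleted: np.ndarray  # observed strictly below the lower CI bound
    ci: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pattern": ["&".join(p) for p in self.patterns],
            "observed": self.observed, "ci_lower": self.lower,
            "ci_upper": self.upper, "depleted": self.depleted,
        })


def _exclusive_pattern_counts(masks: np.ndarray) -> np.ndarray:
    """Sizes of all 2^m - 1 non-empty exclusive membership patterns.

    ``masks`` is (m, n_universe) boolean; pattern index k (1..2^m-1) selects
    elements in exactly the sets whose bit is set in k."""
    m, n = masks.shape
    code = np.zeros(n, dtype=np.int64)
    for i in range(m):
        code |= masks[i].astype(np.int64) << i
    return np.bincount(code, minlength=2 ** m)[1:]


def intersection_null(
    sets: Sequence[Set],
    universes: Sequence[Sequence],
    set_ids: Sequence[str] | None = None,
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.99,
) -> IntersectionNullResult:
    """Empirical CI of every exclusive intersection size under size-matched
    random draws; observed sizes below the lower bound are flagged as
    significantly depleted."""
    m = len(sets)
    if m != len(universes):
        raise ValueError("need one universe per set")
    set_ids = list(set_ids) if set_ids is not None else [f"S{i}" for i in range(m)]
    for s, u in zip(sets, universes):
        if not set(s) <= set(u):
            raise ValueError("each set must lie within its universe")

    union = sorted(set().union(*map(set, universes)))
    pos = {g: i for i, g in enumerate(union)}
    obs_masks = np.zeros((m, len(union)), dtype=bool)
    for i, s in enumerate(sets):
        obs_masks[i, [pos[g] for g in s]] = True
    observed = _exclusive_pattern_counts(obs_masks)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty((n_rand, 2 ** m - 1), dtype=np.int64)
    uni_cols = [np.array([pos[g] for g in u]) for u in universes]
    sizes = [len(s) for s in sets]
    for t in range(n_rand):
        masks = np.zeros((m, len(union)), dtype=bool)
        for i in range(m):
            pick = rng.choice(len(uni_cols[i]), size=sizes[i], replace=False)
            masks[i, uni_cols[i][pick]] = True
        null[t] = _exclusive_pattern_counts(masks)

    tail = (1 - ci) / 2
    lower = np.quantile(null, tail, axis=0)
    upper = np.quantile(null, 1 - tail, axis=0)
    patterns = []
    for k in range(1, 2 ** m):
        patterns.append(tuple(set_ids[i] for i in range(m) if k >> i & 1))
    return IntersectionNullResult(patterns=patterns, observed=observed,
                                  lower=lower, upper=upper,
                                  depleted=observed < lower, ci=ci)
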