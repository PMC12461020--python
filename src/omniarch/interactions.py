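"""Pairwise genetic-interaction classification from perturbation vectors.

Given post-perturbation differential-expression vectors A, B (single
perturbations) and AB (co-perturbation) over a shared gene dimension, an
ordinary least-squares fit without intercept of c1*A + c2*B ≈ AB yields

* magnitude = (c1² + c2²)^0.5 — low values indicate suppression (the joint
  effect is weaker than the sum of individual effects), high values synergy;
* model_fit = Pearson corr(c1*A + c2*B, AB) — low values indicate
  neomorphism (the joint effect is not a linear blend of the individual
  effects at all).

The group composition of the strongest suppression (lowest magnitude) and
neomorphism (lowest model fit) effects is compared to the global group
distribution with a chi-squared goodness-of-fit test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionTriple", "InteractionResult", "TripleSet",
    "InteractionModel", "InteractionResults",
    "fit_interaction", "fit_triple_set", "rank_and_test", "RankTestResult",
]

logger = logging.getLogger(__name__)

_COND_WARN = 1e8


@dataclass
class InteractionTriple:
    """One (A, B, AB) triple with its gene pair and pair-group label."""

    pair: Tuple[str, str]
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.AB = np.asarray(self.AB, dtype=float)
        if not (self.A.shape == self.B.shape == self.AB.shape):
            raise ValueError("A, B, AB must share one gene dimension")
        if self.A.ndim != 1 or self.A.size < 3:
            raise ValueError("vectors must be 1-D with length >= 3")
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair genes must be distinct")


@dataclass
class InteractionResult:
    """Coefficients and diagnostics of one no-intercept interaction fit."""

    pair: Tuple[str, str]
    c1: float
    c2: float
    magnitude: float
    model_fit: float
    group: str = ""


class InteractionModel:
    """OLS interaction model c1*A + c2*B = AB for one triple.

    ``fit()`` returns :class:`InteractionResults` carrying the
    coefficients, magnitude, model fit and a ``summary()``.
    """

    def __init__(self, triple: InteractionTriple):
        self.triple = triple
        if not self.triple.A.any() and not self.triple.B.any():
            raise ValueError("A and B are both zero; the fit is undefined")

    def fit(self) -> "InteractionResults":
        t = self.triple
        X = np.column_stack([t.A, t.B])
        sv = np.linalg.svd(X, compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        if cond > _COND_WARN:
            warnings.warn(f"A and B are nearly collinear (cond={cond:.2e}); "
                          "coefficients are poorly determined")
        coef, *_ = np.linalg.lstsq(X, t.AB, rcond=None)
        c1, c2 = float(coef[0]), float(coef[1])
        fitted = X @ coef
        if np.ptp(t.AB) == 0:
            model_fit = np.nan  # constant AB: correlation undefined
        elif np.var(fitted) < 1e-24:
            model_fit = 0.0     # fitted vector ~constant: no linear signal
        else:
            model_fit = float(stats.pearsonr(fitted, t.AB).statistic)
        return InteractionResults(
            model=self,
            result=InteractionResult(pair=t.pair, c1=c1, c2=c2,
                                     magnitude=float(np.hypot(c1, c2)),
                                     model_fit=model_fit, group=t.group),
            condition_number=float(cond),
        )


@dataclass
class InteractionResults:
    model: InteractionModel
    result: InteractionResult
    condition_number: float

    def __getattr__(self, name):
        return getattr(self.result, name)

    def summary(self) -> str:
        r = self.result
        return "\n".join([
            "Interaction fit (c1*A + c2*B = AB, no intercept)",
            f"pair: {r.pair[0]} x {r.pair[1]}" + (f" [{r.group}]" if r.group else ""),
            f"c1 = {r.c1:.4f}, c2 = {r.c2:.4f}",
            f"magnitude = {r.magnitude:.4f} (low: suppression, high: synergy)",
            f"model fit = {r.model_fit:.4f} (low: neomorphism)",
            f"condition number = {self.condition_number:.3g}",
        ])


def fit_interaction(triple: InteractionTriple) -> InteractionResult:
    """Least-squares fit of one triple; see :class:`InteractionModel`."""
    return InteractionModel(triple).fit().result


@dataclass
class TripleSet:
    """Dense container of many triples over one gene dimension."""

    A: np.ndarray   # (n_triples, n_genes)
    B: np.ndarray
    AB: np.ndarray
    pairs: List[Tuple[str, str]]
    groups: List[str]

    def __post_init__(self):
        if not (self.A.shape == self.B.shape == self.AB.shape):
            raise ValueError("A, B, AB arrays must agree in shape")
        if len(self.pairs) != len(self.A) or len(self.groups) != len(self.A):
            raise ValueError("pairs/groups must match the number of triples")

    def __len__(self) -> int:
        return len(self.A)

    def __getitem__(self, i: int) -> InteractionTriple:
        return InteractionTriple(pair=self.pairs[i], A=self.A[i], B=self.B[i],
                                 AB=self.AB[i], group=self.groups[i])

    def to_npz(self, path) -> None:
        np.savez(path, A=self.A, B=self.B, AB=self.AB,
                 pair_a=np.array([p[0] for p in self.pairs]),
                 pair_b=np.array([p[1] for p in self.pairs]),
                 group=np.array(self.groups))

    @classmethod
    def from_npz(cls, path) -> "TripleSet":
        with np.load(path, allow_pickle=False) as d:
            pairs = list(zip(d["pair_a"].tolist(), d["pair_b"].tolist()))
            return cls(A=d["A"], B=d["B"], AB=d["AB"], pairs=pairs,
                       groups=d["group"].tolist())


def fit_triple_set(triples: TripleSet) -> pd.DataFrame:
    """Fit every triple; returns a frame (pair, group, c1, c2, magnitude,
    model_fit)."""
    rows = []
    for i in range(len(triples)):
        r = fit_interaction(triples[i])
        rows.append({"pair": f"{r.pair[0]}|{r.pair[1]}", "group": r.group,
                     "c1": r.c1, "c2": r.c2, "magnitude": r.magnitude,
                     "model_fit": r.model_fit})
    return pd.DataFrame(rows)


@dataclass
class RankTestResult:
    """Group composition of a top-k tail against the global distribution."""

    criterion: str          # "suppression" or "neomorphism"
    k: int
    observed: pd.Series     # group -> count in top k
    expected: pd.Series     # group -> k * global frequency
    chi2: float
    pvalue: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"observed": self.observed,
                             "expected": self.expected,
                             "obs_minus_exp": self.observed - self.expected})


def _topk_tail(frame: pd.DataFrame, value_col: str, k: int) -> pd.DataFrame:
    # stable sort by (value, pair) for reproducible tie-breaking
    return frame.sort_values([value_col, "pair"], kind="mergesort").head(k)


def rank_and_test(
    results: pd.DataFrame,
    k: int = 100,
    criteria: Sequence[str] = ("suppression", "neomorphism"),
) -> List[RankTestResult]:
    """Chi-squared goodness-of-fit of the pair-group composition among the
    k strongest suppression (lowest magnitude) and neomorphism (lowest
    model fit) effects, against expected proportions equal to the global
    group frequencies among all results."""
    required = {"pair", "group", "magnitude", "model_fit"}
    if not required <= set(results.columns):
        raise ValueError(f"results frame must have columns {sorted(required)}")
    if k > len(results):
        raise ValueError(f"k={k} exceeds the {len(results)} available results")
    if results["group"].isna().any() or (results["group"] == "").any():
        raise ValueError("every result must carry a group label")

    global_freq = results["group"].value_counts(normalize=True).sort_index()
    out = []
    for criterion in criteria:
        col = {"suppression": "magnitude", "neomorphism": "model_fit"}[criterion]
        sub = results.dropna(subset=[col])
        top = _topk_tail(sub, col, k)
        observed = top["group"].value_counts().reindex(global_freq.index, fill_value=0)
        expected = global_freq * len(top)
        tiny = expected <= 0
        if tiny.any():
            logger.warning("groups with zero expectation merged into 'other'")
            keep = ~tiny
            observed = pd.concat([observed[keep],
                                  pd.Series({"other": observed[tiny].sum()})])
            expected = pd.concat([expected[keep],
                                  pd.Series({"other": expected[tiny].sum()})])
        chi2, p = stats.chisquare(observed.to_numpy(), expected.to_numpy())
        out.append(RankTestResult(criterion=criterion, k=k, observed=observed,
                                  expected=expected, chi2=float(chi2),
                                  pvalue=float(p)))
    return out
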