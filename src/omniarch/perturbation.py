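"""Per-perturbagen discriminative testing of core- vs peripheral-gene response.

A perturbagen (a knocked-down or overexpressed gene) is *discriminative*
for a trait when the differential-expression Z scores it induces on the
trait's core genes differ significantly from those of peripheral genes.
The screen runs one Welch t test per perturbagen (mean contrast) and one
upper-tail F test (core-variance increase), adjusts each family with
Benjamini-Hochberg across all perturbagens of the panel, and reports the
fraction of perturbagens significant at FDR < alpha.

The model/results split follows the statsmodels convention:

>>> model = DiscriminativePerturbationModel(panel, core, peripheral)
>>> res = model.fit()
>>> res.fraction_significant
>>> res.summary()
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

__all__ = [
    "PerturbationPanel",
    "DiscriminativePerturbationModel", "DiscriminativeResults",
    "aggregate_signatures", "discriminative_test", "variance_test",
    "random_set_control", "proportion_ztest", "normal_upper_tail",
    "response_correlation", "ResponseCorrelationSummary",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # variance floor guarding exact-separation degenerate inputs


@dataclass
class PerturbationPanel:
    """A perturbagen x measured-gene matrix of differential-expression
    Z scores for one cell line and perturbation type (a LINCS-style
    consensus-signature panel)."""

    cell_line: str
    perturbation_type: str
    z: pd.DataFrame  # index: perturbagens, columns: measured genes

    def __post_init__(self):
        if self.z.index.duplicated().any():
            raise ValueError("duplicate perturbagens in panel")
        if self.z.columns.duplicated().any():
            raise ValueError("duplicate measured genes in panel")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("panel Z scores must be finite")

    @property
    def perturbagens(self) -> List[str]:
        return list(self.z.index)

    @property
    def measured_genes(self) -> List[str]:
        return list(self.z.columns)


def aggregate_signatures(replicates: Sequence[Sequence[float]]) -> np.ndarray:
    """Consensus signature as the unweighted element-wise mean of replicate
    Z vectors (the aggregation used for sparsely replicated perturbagens)."""
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    arrs = [np.asarray(r, dtype=float) for r in replicates]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("replicate length mismatch")
    return np.mean(arrs, axis=0)


def _moments_with_self_exclusion(
    z: np.ndarray, cols: np.ndarray, own_col: np.ndarray, own_val: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row mean/variance over ``cols`` with the perturbagen's own gene
    removed from the set when it belongs to it.  Returns (n, mean, var)."""
    sub = z[:, cols]
    s1 = sub.sum(axis=1)
    s2 = np.square(sub).sum(axis=1)
    n = np.full(z.shape[0], len(cols), dtype=float)
    in_set = np.isin(own_col, cols)
    s1 = np.where(in_set, s1 - own_val, s1)
    s2 = np.where(in_set, s2 - np.square(own_val), s2)
    n = np.where(in_set, n - 1, n)
    mean = s1 / n
    var = np.maximum((s2 - np.square(s1) / n) / (n - 1), 0.0)
    return n, mean, var


class DiscriminativePerturbationModel:
    """Per-perturbagen core-vs-peripheral contrast on a signature panel.

    Parameters
    ----------
    panel : PerturbationPanel
    core, peripheral : gene sets to contrast (intersected with the panel's
        measured genes; the perturbagen's own gene is dropped from both
        sets for its own test unless ``exclude_self=False``).
    alpha : FDR significance level (default 0.05).
    min_class_size : floor on measured genes per class (default 10).
    equal_var : use Student instead of Welch t (default False, i.e. Welch;
        the class sizes are typically very unequal).
    """

    def __init__(self, panel: PerturbationPanel, core: Iterable[str],
                 peripheral: Iterable[str], alpha: float = 0.05,
                 min_class_size: int = 10, exclude_self: bool = True,
                 equal_var: bool = False):
        self.panel = panel
        measured = pd.Index(panel.measured_genes)
        self.core = [g for g in measured if g in set(core)]
        self.peripheral = [g for g in measured if g in set(peripheral)]
        if set(self.core) & set(self.peripheral):
            raise ValueError("core and peripheral sets overlap")
        for name, genes in (("core", self.core), ("peripheral", self.peripheral)):
            if len(genes) < min_class_size:
                raise ValueError(
                    f"only {len(genes)} {name} genes among measured genes "
                    f"(floor {min_class_size})")
        self.alpha = alpha
        self.exclude_self = exclude_self
        self.equal_var = equal_var
        self._measured = measured

    def fit(self) -> "DiscriminativeResults":
        z = self.panel.z.to_numpy()
        measured = self._measured
        core_cols = measured.get_indexer(self.core)
        peri_cols = measured.get_indexer(self.peripheral)

        own_col = measured.get_indexer(self.panel.perturbagens)
        rows = np.arange(z.shape[0])
        own_val = np.where(own_col >= 0, z[rows, np.clip(own_col, 0, None)], 0.0)
        if not self.exclude_self:
            own_col = np.full_like(own_col, -1)

        nc, mc, vc = _moments_with_self_exclusion(z, core_cols, own_col, own_val)
        npr, mp, vp = _moments_with_self_exclusion(z, peri_cols, own_col, own_val)

        if self.equal_var:
            sp2 = ((nc - 1) * vc + (npr - 1) * vp) / (nc + npr - 2)
            se = np.sqrt(np.maximum(sp2 * (1 / nc + 1 / npr), _EPS))
            df = nc + npr - 2
        else:
            a, b = vc / nc, vp / npr
            se = np.sqrt(np.maximum(a + b, _EPS))
            with np.errstate(divide="ignore", invalid="ignore"):
                df = np.square(a + b) / (np.square(a) / (nc - 1) + np.square(b) / (npr - 1))
            df = np.where(np.isfinite(df), df, nc + npr - 2)
        t = (mc - mp) / se
        p_mean = 2.0 * stats.t.sf(np.abs(t), df)

        with np.errstate(divide="ignore"):
            f = vc / np.maximum(vp, _EPS)
        p_var = stats.f.sf(f, nc - 1, npr - 1)

        frame = pd.DataFrame({
            "perturbagen": self.panel.perturbagens,
            "mean_diff": mc - mp, "t_stat": t, "p_mean": p_mean,
            "fdr_mean": bh_fdr(p_mean),
            "f_stat": f, "p_var": p_var, "fdr_var": bh_fdr(p_var),
            "n_core": nc.astype(int), "n_periph": npr.astype(int),
        })
        return DiscriminativeResults(model=self, frame=frame, alpha=self.alpha,
                                     zero_peripheral_variance=bool((vp <= 0).any()))


@dataclass
class DiscriminativeResults:
    """Fit results of :class:`DiscriminativePerturbationModel`."""

    model: DiscriminativePerturbationModel
    frame: pd.DataFrame
    alpha: float = 0.05
    zero_peripheral_variance: bool = False

    @property
    def fraction_significant(self) -> float:
        """Fraction of perturbagens with mean-contrast FDR < alpha."""
        return float((self.frame["fdr_mean"] < self.alpha).mean())

    @property
    def fraction_variance_significant(self) -> float:
        """Fraction with significant core-variance increase (FDR < alpha)."""
        return float((self.frame["fdr_var"] < self.alpha).mean())

    @property
    def significant_perturbagens(self) -> Set[str]:
        m = self.frame["fdr_mean"] < self.alpha
        return set(self.frame.loc[m, "perturbagen"])

    @property
    def variance_significant_perturbagens(self) -> Set[str]:
        m = self.frame["fdr_var"] < self.alpha
        return set(self.frame.loc[m, "perturbagen"])

    def fraction_by_class(self, classes: Dict[str, Set[str]]) -> pd.DataFrame:
        """Significant fraction split by perturbagen class (core / peripheral
        / hsp / gwas ...): one row per class with n and fraction."""
        rows = []
        sig = self.frame["fdr_mean"] < self.alpha
        for name, members in classes.items():
            mask = self.frame["perturbagen"].isin(set(members))
            n = int(mask.sum())
            rows.append({"class": name, "n": n,
                         "n_significant": int((sig & mask).sum()),
                         "fraction": float((sig & mask).sum() / n) if n else np.nan})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.model.panel
        lines = [
            "Discriminative perturbation screen",
            "==================================",
            f"panel: {p.cell_line} / {p.perturbation_type} "
            f"({len(p.perturbagens)} perturbagens x {len(p.measured_genes)} genes)",
            f"core genes measured: {len(self.model.core)}; "
            f"peripheral: {len(self.model.peripheral)}",
            f"t test: {'Student' if self.model.equal_var else 'Welch'}, two-sided; "
            f"self-exclusion: {self.model.exclude_self}",
            f"FDR < {self.alpha}: {self.fraction_significant:.3f} discriminative, "
            f"{self.fraction_variance_significant:.3f} variance-increased",
        ]
        return "\n".join(lines)


def discriminative_test(
    panel: PerturbationPanel, core: Iterable[str], peripheral: Iterable[str],
    **kwargs,
) -> DiscriminativeResults:
    """Functional entry point for the per-perturbagen Welch screen."""
    return DiscriminativePerturbationModel(panel, core, peripheral, **kwargs).fit()


def variance_test(
    panel: PerturbationPanel, core: Iterable[str], peripheral: Iterable[str],
    **kwargs,
) -> pd.DataFrame:
    """Per-perturbagen one-sided F tests (core variance greater), BH-adjusted.

    Raises if any perturbagen has zero peripheral variance (the ratio is
    then undefined).
    """
    res = DiscriminativePerturbationModel(panel, core, peripheral, **kwargs).fit()
    if res.zero_peripheral_variance:
        raise ValueError("zero peripheral variance for at least one perturbagen")
    return res.frame[["perturbagen", "f_stat", "p_var", "fdr_var",
                      "n_core", "n_periph"]].copy()


def random_set_control(
    panel: PerturbationPanel,
    universe: Sequence[str],
    set_size: int,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    **kwargs,
) -> np.ndarray:
    """Null distribution of the discriminative fraction for random "core"
    sets of ``set_size`` drawn from ``universe`` (complement as peripheral),
    repeated ``n_reps`` times."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = [g for g in universe if g in set(panel.measured_genes)]
    if set_size > len(universe):
        raise ValueError("set_size exceeds the usable universe")
    fractions = np.empty(n_reps)
    for i in range(n_reps):
        fake_core = set(rng.choice(universe, size=set_size, replace=False))
        fake_peri = set(universe) - fake_core
        res = DiscriminativePerturbationModel(
            panel, fake_core, fake_peri, alpha=alpha, **kwargs).fit()
        fractions[i] = res.fraction_significant
    return fractions


def normal_upper_tail(z: float) -> float:
    """Upper-tail standard normal probability P[Z >= z]."""
    return float(stats.norm.sf(z))


def proportion_ztest(k1: int, n1: int, k2: int, n2: int,
                     alternative: str = "greater") -> Tuple[float, float]:
    """Pooled two-proportion Z test.

    Z = (k1/n1 - k2/n2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2)/(n1 + n2); the one-sided p is the upper normal tail of
    Z (``alternative="greater"``), or twice the tail of \\|Z\\| for
    ``"two-sided"``.  A degenerate pooled proportion (0 or 1) yields p = 1
    with a warning (no evidence either way).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("need 0 <= k <= n and n >= 1")
    phat = (k1 + k2) / (n1 + n2)
    if phat in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; p set to 1")
        return 0.0, 1.0
    z = (k1 / n1 - k2 / n2) / np.sqrt(phat * (1 - phat) * (1 / n1 + 1 / n2))
    if alternative == "greater":
        p = normal_upper_tail(z)
    elif alternative == "two-sided":
        p = 2 * normal_upper_tail(abs(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


@dataclass
class ResponseCorrelationSummary:
    """Pairwise Spearman correlation summary of core-gene response vectors."""

    n_pairs: int
    n_excluded: int
    frac_below: float   # fraction of pairs with rho < lower threshold
    frac_above: float   # fraction of pairs with rho > upper threshold
    thresholds: Tuple[float, float] = (0.25, 0.5)


def response_correlation(
    panel: PerturbationPanel,
    core: Iterable[str],
    significant: Iterable[str],
    thresholds: Tuple[float, float] = (0.25, 0.5),
) -> ResponseCorrelationSummary:
    """Pairwise Spearman rho between core-gene response vectors of the
    significant perturbagens; reports the fractions of pairs below/above
    the stated thresholds on the signed rho.  Pairs involving a constant
    vector (rho undefined) are excluded and counted."""
    core = [g for g in panel.measured_genes if g in set(core)]
    sig = [p for p in panel.perturbagens if p in set(significant)]
    if len(sig) < 2:
        raise ValueError("need at least 2 significant perturbagens")
    if len(core) < 3:
        raise ValueError("need at least 3 measured core genes")
    mat = panel.z.loc[sig, core].to_numpy()  # perturbagens x core genes
    constant = np.ptp(mat, axis=1) == 0
    # Spearman rho = Pearson correlation of ranks; constant vectors give NaN
    ranks = stats.rankdata(mat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    iu = np.triu_indices(len(sig), k=1)
    vals = rho[iu]
    bad = constant[iu[0]] | constant[iu[1]] | ~np.isfinite(vals)
    vals = vals[~bad]
    lo, hi = thresholds
    return ResponseCorrelationSummary(
        n_pairs=int(vals.size), n_excluded=int(bad.sum()),
        frac_below=float((vals < lo).mean()) if vals.size else np.nan,
        frac_above=float((vals > hi).mean()) if vals.size else np.nan,
        thresholds=thresholds,
    )
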