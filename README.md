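# omniarch

Analysis toolkit for exploring the **omnigenic architecture** of complex
traits.  The omnigenic model posits that a small set of *core genes* has
direct effects on a trait while the vast majority of *peripheral genes*
acts indirectly, by concertedly modulating core-gene expression and
function through cellular networks.  `omniarch` implements the statistical
machinery for probing that architecture with gene classifications, tissue
expression, genome-scale perturbation panels, set-overlap statistics,
network propagation and co-perturbation interaction classification — all
exercisable end to end on a bundled synthetic-data generator with planted
ground truth.

It is aimed at computational biologists who have (or simulate) gene-level
consensus scores, GWAS summary signals, LINCS-style perturbation
signatures and multi-modal molecular networks, and want tested, seeded,
reproducible implementations of the downstream statistics.

## What it computes

**Gene classes.** Genes with consensus score (CS) 11 plus the
Mendelian-disorder (OMIM-derived) training genes are *core*; genes with
CS 0 are *peripheral*; CS 1–10 are excluded.  *Highly significant
peripheral genes* (HSPs) are peripheral genes with gene-level GWAS
`Z > 5`, or genes < 10 kb from genome-wide-significant SNPs
(`p ≤ 5×10⁻⁸`) after discarding SNPs < 10 kb from any CS > 0 gene or
sharing an LD block with core/OMIM genes.

**Discriminative perturbagens.**  For each perturbagen in a signature
panel (perturbagen × gene differential-expression Z scores), a two-sided
Welch t test compares core- versus peripheral-gene responses, with
Benjamini–Hochberg FDR across the panel; a one-sided F test screens for
core-variance increases.  Random-gene-set controls quantify the null rate,
and a pooled two-proportion Z test compares discriminative rates between
perturbagen classes.

**Set overlap.**  `Overlap(A,B) = |A∩B| / min(|A|,|B|)` between
discriminative sets from different panels, with an empirical p-value from
1,000 size-matched resampled pairs: rank `r` of the observed coefficient
is transformed via `r′ = r/1001`, `p = min(r′, 1−r′)×2`.  UpSet-style
exclusive intersections get empirical 99% null CIs.

**Genetic interactions.**  For perturbation vectors A, B and
co-perturbation AB, an ordinary least-squares fit without intercept of
`c₁A + c₂B = AB` yields `magnitude = (c₁² + c₂²)^0.5` (low ⇒ suppression,
high ⇒ synergy) and `model_fit = corr(c₁A + c₂B, AB)` (low ⇒
neomorphism); the gene-class composition of the top-k strongest effects is
tested with a χ² goodness-of-fit test against the global distribution.

**Networks.**  Typed directed multigraphs (PPIs doubled into opposite
directed edges); betweenness/degree/PageRank on the collapsed simple
graph with Mann–Whitney class comparisons; random-walk-with-restart label
propagation; min-max scaled, ensemble-averaged, core-gene-maxed
attribution aggregation; exact binomial edge-type composition tests.

## Worked example

```python
import pandas as pd
import omniarch as oa
from omniarch.config import SyntheticConfig
from omniarch import gene_sets

cfg = SyntheticConfig(seed=1)           # 2,200 genes, 200 core, 1,000 perturbagens
ds = oa.generate_all(cfg)               # synthetic bundle with planted truth

scores = pd.Series(ds.genes["consensus_score"].to_numpy(), index=ds.genes["symbol"])
omim = set(ds.genes.loc[ds.genes["is_omim"], "symbol"])
cls = gene_sets.classify_genes(scores, omim)

res = oa.DiscriminativePerturbationModel(ds.panel, cls.core, cls.peripheral).fit()
print(res.summary())
```

prints

```
Discriminative perturbation screen
==================================
panel: SYN1 / knockdown (1000 perturbagens x 2200 genes)
core genes measured: 200; peripheral: 1780
t test: Welch, two-sided; self-exclusion: True
FDR < 0.05: 0.316 discriminative, 0.050 variance-increased
```

The generator planted a 0.5-Z mean shift on core genes for 30% of
perturbagens and a doubled core SD for 5%; the screen recovers 31.6% and
5.0% — the planted rates within sampling error.  Interaction fits read the
same way:

```python
from omniarch.interactions import InteractionTriple, InteractionModel
r = InteractionModel(InteractionTriple(("NFKB1", "MAP2K3"), A, B, AB)).fit()
print(r.summary())
```

```
Interaction fit (c1*A + c2*B = AB, no intercept)
pair: NFKB1 x MAP2K3
c1 = 0.1838, c2 = 0.2034
magnitude = 0.2741 (low: suppression, high: synergy)
model fit = 0.9265 (low: neomorphism)
condition number = 1.08
```

Here `AB ≈ 0.2(A + B)`, i.e. a suppressive interaction: the fitted
magnitude sits near `0.2·√2 ≈ 0.283` with a high model fit.

A command-line interface mirrors the library
(`omniarch simulate|classify|hsp|enrich|perturb|overlap|interact|netstats|run`);
`omniarch run --outdir out --seed 1` executes the full pipeline and writes
a machine-readable `report.json` plus TSV tables.  Re-running with the
same config is byte-identical.

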