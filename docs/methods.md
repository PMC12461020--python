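# Methods

This note documents the statistical procedures, the synthetic benchmark
they are validated on, and the design choices made where conventions were
genuinely open.

## Gene classification and HSP selection

The gene universe carries an integer consensus score (CS) in 0–11 from an
upstream ensemble core-gene predictor, plus a flag for Mendelian-disorder
(OMIM-derived) training genes.  Core = {CS = 11} ∪ OMIM (OMIM genes are
core regardless of score — they are training labels without scores, and
unlisted OMIM genes are appended to the universe with a warning);
peripheral = {CS = 0} \ OMIM; CS 1–10 form an excluded band that enters no
contrast.

HSPs (highly significant peripherals) are selected two ways.  By score:
peripheral genes with gene-level GWAS `Z` strictly greater than a
threshold (default 5).  By SNP proximity: keep SNPs with `p ≤ 5×10⁻⁸`,
discard those strictly within 10 kb of any CS > 0 gene body or sharing an
LD block with an OMIM or CS-11 gene, then return peripheral genes strictly
within 10 kb of a surviving SNP.  Choices made explicit:

* SNP–gene distance is measured to the **gene body** (0 inside the body,
  else base pairs to the nearest edge), strand-agnostically; the
  alternative (distance to TSS) is not used because none of the analyses
  depends on promoter anatomy.
* "less than 10 kb" is a strict inequality; "5×10⁻⁸ or lower" is `≤`.
* LD blocks are consumed as SNP annotations (fixed-width, non-overlapping
  intervals).  Gene-to-block membership is recovered from the SNP table's
  position→block mapping; when no consistent fixed width exists the LD
  exclusion is skipped with a warning rather than guessed.
* Coordinates are 0-based half-open internally (BED convention); SNP
  tables on disk are 1-based and converted at the reader boundary.

## Enrichment statistics

Tissue expression: genes are ranked per tissue (descending, average ranks
for ties); the "top" set is the requested upper percentile; the 2×2 table
of class × top membership gives a sample odds ratio `ad/bc` with the
Haldane–Anscombe +0.5 correction whenever a cell is zero, and a two-sided
Fisher exact p.  Annotation terms: upper-tail hypergeometric p of the
term/target overlap within the universe (enrichment is directional by
definition).  Validation bins are compared against peripheral genes with
two-sided Fisher tests.  Every "FDR" is Benjamini–Hochberg, applied per
family (terms, bins, tissues-by-class, perturbagens within a panel,
overlap pairs, edge-type-by-trait cells).

Generic attribute comparisons (centralities, TSS/enhancer counts,
propagation scores) use a two-sided Welch t or Mann–Whitney U test; the U
statistic is reported for the first sample, and two identical constant
samples under the t test return p = 1 by convention.

## The discriminative perturbation screen

A panel is a perturbagen × measured-gene matrix of differential-expression
Z scores (a LINCS-style consensus-signature panel); replicate signatures
are aggregated by unweighted element-wise mean.  Per perturbagen the
screen compares core- vs peripheral-gene Z values:

* **Welch t** (two-sided) by default.  Class sizes are grossly unequal
  (hundreds of core vs thousands of peripheral genes), so the
  unequal-variance form is the robust choice; Student's t is available via
  `equal_var=True`.
* The perturbagen's own gene is removed from both comparison sets,
  avoiding the trivial self-knockdown signal; switchable with
  `exclude_self=False`.  Both choices are recorded in `summary()`.
* A variance floor of 1e-12 on the squared standard error guards exact
  separation (all-constant classes); the resulting p-values are
  effectively zero, as intended for that degenerate input.
* One-sided F = s²_core/s²_peripheral (upper tail) screens for variance
  increases of core-gene response; zero peripheral variance is an error.
* BH-FDR is applied across all perturbagens of one panel (one family per
  cell line × perturbation type), and the reported headline number is the
  fraction of perturbagens with FDR < 0.05, overall and per perturbagen
  class.

The implementation is vectorised (per-row moment sums with self-exclusion
corrections) and is verified in the test suite against a per-row
`scipy.stats.ttest_ind` loop.

Controls: `random_set_control` repeats the screen with random "core" sets
of matched size (complement as peripheral); `proportion_ztest` compares
discriminative rates between perturbagen classes with the pooled
two-proportion Z statistic, upper-tail normal p.  Response coherence is
summarised by pairwise Spearman ρ (Pearson on ranks) between core-gene
response vectors of significant perturbagens, reporting the fractions of
pairs below/above thresholds on the **signed** ρ (defaults 0.25 / 0.5);
pairs involving a constant vector are excluded and counted.

## Overlap statistics

`Overlap(A,B) = |A∩B| / min(|A|,|B|)`.  Significance is empirical because
A and B come from different universes: draw `n_rand` (default 1,000)
random sets size-matched to A and B from their universes, pair them
index-wise into `n_rand` null coefficients, take the rank
`r = 1 + #{null < observed}` clamped to `[1, n_rand]`, and transform
`r′ = r/(n_rand+1)`, `p = min(r′, 1−r′)×2`.  The clamped rank prevents
p = 0; ties count toward the conservative side.  A `pairing="cross"` mode
forms all `n_rand²` cross pairs instead; the paired mode is the default.
BH-FDR is applied across all requested pairs.  The Monte-Carlo p is
validated against exhaustive enumeration of all C(10,3)² size-matched
pairs on a 10-element universe.

For multi-set comparisons, every exclusive (UpSet-style) intersection
pattern receives an empirical CI (default 99%) of its size under
size-matched random draws; observed sizes strictly below the lower bound
are flagged as significantly depleted.

## Interaction classification

For a triple (A, B, AB) of perturbation expression vectors, ordinary least
squares **without intercept** fits `c₁A + c₂B ≈ AB` — the model has
exactly two parameters, so no intercept is warranted.  Then
`magnitude = (c₁²+c₂²)^0.5` and `model_fit = Pearson corr(c₁A+c₂B, AB)`.
Degenerate cases: A = B = 0 is an error; constant AB leaves the
correlation undefined (reported missing); a ~zero fitted vector (AB
orthogonal to both inputs) reports model_fit = 0, the no-linear-signal
limit.  Near-collinear A, B trigger a condition-number warning.

Top-k composition: the k results with smallest magnitude (suppression)
and, separately, smallest model fit (neomorphism) are selected with a
stable (value, pair) sort for reproducible tie-breaking; their pair-group
counts are tested against expected proportions equal to the global group
frequencies with a χ² goodness-of-fit test.  Note the test draws k of n
without replacement: it is calibrated for k ≪ n and conservative when k
is a large share of n.  Verbal class labels (suppression/synergy/
neomorphism thresholds) are configuration, not hard-coded — the analyses
report ranked top-k tails rather than absolute cutoffs, and the magnitude
scale depends on how the vectors were normalised upstream.

## Network statistics

The multi-modal network is a typed directed multigraph; undirected PPIs
are stored as two directed edges running in opposite directions.
Centralities (normalized betweenness, in+out degree, PageRank with
damping 0.85) are computed on the simple directed graph obtained by
collapsing parallel typed edges; the typed structure is retained for the
composition analysis.  Label propagation is random walk with restart,
implemented as personalized PageRank with damping 1 − restart (default
restart 0.15) and uniform restart mass on the seeds; scores sum to 1.
The propagation variant and its parameters are recorded in the pipeline
report since several variants exist in the literature.

Attribution aggregation: per ensemble model, input-importance scores are
min-max scaled to [−1, 1] (signed) and edge-importance scores to [0, 1]
(absolute values); scores are averaged across models and, when attributions
are per core gene, each item takes the maximum across core genes.
Constant vectors scale to 0 with a warning.  Edge-type composition above
an importance threshold (default 0.75) uses exact Clopper–Pearson 95% CIs
around the pooled expectation and two-sided exact binomial tests per type
and trait, BH-adjusted; exact rather than normal-approximate intervals
are used because high-importance subnetworks can be small.

## The synthetic benchmark

The generator emulates the input layers of an omnigenic-architecture
study on one synthetic chromosome, with all ground truth emitted as a
sidecar (`truth.tsv`), never inside primary data files.  Defaults define
the benchmark conditions used throughout the tests and the acceptance
script:

* **Universe**: 2,200 genes; 200 core (≈ half OMIM-flagged), 10% excluded
  band (CS 1–10), 10 HSPs; 6 tissues with 2 disease-relevant ones.
  Gaussian expression (base 6, SD 1, clipped at 0) with a +1.0 shift for
  core genes in relevant tissues only; TSS/enhancer counts are negative
  binomial (dispersion 4) with mean 8 for core vs 4 otherwise.  Gaussian
  noise and negative-binomial counts are the simplest structures matching
  the downstream t/F/rank tests.
* **Genome layout**: 2 kb gene bodies, 20 kb fixed LD blocks; scored
  (CS > 0) genes occupy every other block at the chromosome start,
  peripheral genes follow after a buffer.  The spacing makes the planted
  SNP structure unambiguous: every HSP gets a significant SNP 2 kb
  upstream; decoy significant SNPs are planted 3 kb from scored genes
  (proximity exclusion) and inside core-gene LD blocks but outside every
  window (LD exclusion), so both rules are exercised and exact recovery
  of the planted HSP set is the correctness criterion.
* **Panel**: 1,000 perturbagens × all genes, iid N(0,1) baseline — the
  marginal null of LINCS consensus Z scores is not documented, so the
  standard normal is assumed and configurable.  30% of perturbagens add a
  0.5-Z mean shift to core genes with a random per-perturbagen sign
  (up- and downregulation are equally common in real panels); a disjoint
  5% multiply core entries by 2.  At these sizes the Welch noncentrality
  `δ/√(1/200 + 1/1800) ≈ 6.7` puts recovery power near 1, which is what
  makes the ±0.05 recovery band a sharp test.
* **Triples**: 50 per class over 50 genes; additive `AB = A+B+ε`,
  suppression `0.2(A+B)+ε`, synergy `2(A+B)+ε`, neomorphic
  `(1−q)(A+B) + qW` with `q = 0.9` and W Gram–Schmidt-orthogonalised
  against span(A, B) and rescaled to |A+B|.  Suppression and neomorphic
  triples fall on core-core pairs with probability 0.9 (1.0 in the
  acceptance run), emulating planted genetic-interaction structure.
* **Network**: 4,000 drawn edges with endpoint probability ∝ 3 for core
  genes (elevated expected degree), 50% PPI (doubled), 40% regulatory
  (tissue-tagged), 10% metabolic.
* **Annotations**: 30 GMT terms, 5 with 10× core-weighted membership,
  plus one term equal to the exact core set; empty terms are never
  emitted.

What the generator does **not** emulate: realistic LD (no haplotypes),
expression covariance across tissues, signature correlation structure
between perturbagens, scale-free degree distributions, or sequence-level
data.  Passing tests therefore demonstrate correctness of the statistics
and recoverability of planted effects under idealised noise — not
robustness to the correlated noise of real panels.

## Determinism

Every random draw flows from one master seed through named sub-streams
(`SeedSequence` keyed by a CRC of the stage name), so stages are
independently reproducible and the full pipeline rerun is byte-identical
(floats are serialized with a fixed `%.10g` format; no timestamps are
written).  Problem sizes in the test-suite calibration checks (e.g.
1,000-perturbagen panels, 100 random-set repetitions, 1,000 resampling
draws) match the benchmark defaults above.

## Known limitations

* The χ² composition test is conservative for large k/n (documented
  above); an exact multivariate-hypergeometric test would remove this but
  is unnecessary for the k ≪ n regime the analyses use.
* The screen treats measured genes as exchangeable within classes;
  gene–gene correlation in real signature panels would inflate the
  effective FDR relative to the iid calibration shown here.
* `edge_composition` expects a single pooled expectation per edge type;
  trait-specific network sizes are handled, but nested designs (cell type
  × trait) need one call per stratum.
* The LD-block width recovery requires a consistent fixed-width mapping;
  irregular empirical blocks should instead be supplied as an explicit
  SNP annotation (which is the supported input path).
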