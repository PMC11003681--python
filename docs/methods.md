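# Methods

## Model and assumptions

`implinet` treats each omic feature (gene transcript, CpG probe) as
approximately bimodal across samples: a low and a high regime whose
boundary is feature-specific. Boolean implications are statements about the
*joint* occupancy of those regimes for a feature pair — "A high ⇒ B low"
holds when the high-high quadrant of the pair's 2×2 low/high table is
nearly empty relative to what the marginal totals predict under
independence. This captures asymmetric relations that correlation-based
network inference misses, at the cost of assuming that a single threshold
per feature is meaningful. Features that are not bimodal (degenerate step
fit, or fewer than `min_group` samples on either side of the threshold) are
excluded from pair enumeration rather than forced into the model.

The multi-layer construction assumes that the biological coupling between
expression and methylation is mediated by gene identity: inter-layer edges
link nodes representing the same gene, in all three layer pairs
(mRNA↔MP, MP↔CH3 and the direct mRNA↔CH3 pair; the latter can be disabled
with `include_mrna_ch3: false` for users who want all cross-omic traffic
routed through the metapathway).

## Estimators and formulas

- One-step fit: on the sorted vector, split position k minimizes
  `SSE(k) = Σ_left (x − μ_low)² + Σ_right (x − μ_high)²`; ties go to the
  smallest k; threshold = (μ_low + μ_high)/2. A fit is degenerate when the
  best step reduces the zero-step SSE by less than 1e−12 relative — the
  tolerance only needs to separate "numerically flat" from "any real step".
- Sparsity: `s = (e − o)/√e`, `err = ½(o/row + o/col)`, `e = row·col/n`.
  A quadrant is sparse iff `s > s_threshold` **and** `err < p_cutoff`. The
  error-rate bound is the maximum-likelihood prediction-error reading of
  the method's "p-value cutoff"; it is what keeps a populated quadrant with
  a large margin product from being called sparse on the s statistic alone.
  Patterns with one sparse quadrant map to the four asymmetric types
  (sparse ll → low⇒high, lh → low⇒low, hl → high⇒high, hh → high⇒low);
  {lh, hl} → equivalent, {ll, hh} → opposite; any other multi-sparse
  pattern (an entire empty row/column, 3–4 sparse quadrants) is degenerate
  and yields no edge.
- Permutation FDR: every permutation round shuffles each feature's values
  across samples independently, preserving marginals and step thresholds in
  distribution while destroying all pairwise structure;
  `FDR = mean(permuted edge count)/observed edge count` (NaN when nothing
  is observed).
- Differential percentage: `100 · |layer nodes exclusive to condition X| /
  |layer nodes of condition X|`, optionally with the numerator restricted
  to a chromosome (the denominator never is). Reported to two decimals.
  Both directions are always reported with each network's own layer size as
  denominator — the published tables leave the DIS denominator ambiguous,
  and the symmetric choice is recorded in the report metadata.
- Over-representation: hypergeometric upper tail `P(X ≥ k)` for overlap k
  of a query of n in a set of K over a universe of N, BH-adjusted across
  sets. The default universe is the gene content of the relevant network
  layer (configurable).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 1 | added to TPM before log2, maps TPM = 0 to 0 |
| `epsilon` | 1e−6 | β clipped to [ε, 1−ε] so M-values stay finite |
| `margin` | 0.5 | intermediate half-width around the step threshold, on the log2/M scale |
| `s_expression` | 2 | sparsity threshold for expression runs (published cohort-scale setting) |
| `s_methylation` | 4 | sparsity threshold for methylation runs |
| `p_cutoff` | 0.01 | error-rate bound for declaring a quadrant sparse |
| `n_perm` | 20 | permutation rounds for the FDR estimate |
| `min_group` | 5 | minimum samples on each side of a feature's threshold |
| `max_path_len` | 6 | path-length cutoff (edges) for cross-layer queries; 6 spans mRNA→MP→CH3 with slack, unbounded search is intractable |
| `alpha` | 0.05 | BH-adjusted significance level for DE labels and enrichment |

DE/DM labels (`OVER_T`/`DOWN_T`) are produced by a per-feature Welch t-test
with BH adjustment. The labels only annotate nodes for querying; they do
not gate network construction, so the simpler test (rather than a
moderated linear model) is adequate and keeps the dependency surface small.

## Synthetic study conditions

The generator's defaults are the package's reference conditions: 60 genes
and 40 probes, 40 samples per condition, noise σ = 0.25 around modes
separated by ≥ 4σ (log2 modes 2/8, M-value modes ±3), twelve planted
expression pairs covering all six implication types, six planted
methylation pairs, and an 8-gene chromosome-20 aberration block (with six
promoter probes) co-activated only in GAIN samples.

Planted pairs are realized by *mode occupancy*: the joint quadrant labels
are drawn with exact cell counts and shuffled over samples, then values are
drawn around the corresponding modes. At n = 40 the symmetric plants use a
20/20 split of the two dense quadrants (sparse-quadrant expectation
20·20/40 = 10, s = √10 ≈ 3.16) and the asymmetric plants a 19/19/2 split
(expectation 19·19/40 ≈ 9.03, s ≈ 3.004), both chosen from this arithmetic
so the planted sparse quadrant clears s = 3 deterministically while the
third populated quadrant stays below it. Toy-scale runs therefore use s = 3
for both modalities; the cohort-scale defaults (s = 2 expression, s = 4
methylation) remain the CLI defaults for real data.

What the generator does *not* emulate: realistic 450k probe geometry and
probe-level noise structure, copy-number dosage effects on expression
level (the block acts through co-regulation, not mean shift), batch
effects, and the scale of real cohorts (tens of thousands of features).
Passing tests show the estimators and bookkeeping are correct and the
planted causal structure is recoverable; they do not certify threshold
choices for TCGA-sized data.

## Numerical choices and degenerate inputs

- Step-fit ties resolve to the smallest split index; SSE comparisons use a
  relative 1e−12 tolerance so floating-point noise cannot flip a tie.
- Constant features: degenerate fit, all-intermediate labels, excluded from
  pairs; a fully constant matrix makes the FDR undefined (NaN sentinel).
- Zero-variance-in-both-groups features get p = 1 in differential labelling.
- Quadrants with a zero margin total are flagged untestable and never sparse.
- Duplicate edges in inputs are deduplicated with a logged count; inter
  edges are stored once (canonical endpoint order) and traversed both ways.
- All orderings (features, nodes, edges, JSON keys) are sorted, and every
  random draw flows from one seeded generator, so identical configurations
  reproduce byte-identical artifacts.

## Open design points, as resolved here

- CH3 nodes are probe-level; gene-level figures are produced by grouping
  probes per owning gene at report time, so both the probe-resolution CpG
  analysis and the gene-resolution node counts stay available.
- A probe annotated with several region categories counts once per category.
- Cross-modality implications of a feature with itself are not computed at
  the pair-enumeration stage; same-gene coupling enters only through
  inter-layer edges.
- Chromosome filters match the chromosome string, with an arm-suffix form
  ("8q") matching chromosome 8 plus arm annotation q.
- Neo4j is optional: the Cypher export reproduces the graph for users who
  want a live database; all queries run in-process on the same structures.

## Known limitations

All-pairs enumeration is O(F²) in features — fine at annotation-filtered or
toy scale, slow for full 450k methylation arrays (the published workflow has
the same property). The intermediate margin is a fixed width on the
transformed scale rather than adaptive per feature. The enrichment module
implements set over-representation only, not topology-aware or ranked
(GSEA-style) tests.
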