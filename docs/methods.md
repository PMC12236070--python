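# Methods

## Enrichment scoring

AUCell-style scoring treats each cell independently. Genes are ranked by
decreasing expression; ties — ubiquitous in zero-inflated counts — are
broken either by a seeded random permutation applied before a stable
sort (`seeded_shuffle`, the default: unbiased across tied genes yet
exactly reproducible) or by input gene order (`stable_index`, used where
tests need hand-computable ranks). With *G* genes, top fraction *q* and
cutoff *T* = max(1, ⌊qG⌋), a set with *m* members in the matrix scores

    score = Σ_{k≤T} R(k) / Σ_{k≤T} min(k, m),

where R(k) is the number of members among the top-k genes. The
normalization makes 1 mean "the set occupies the very top of the
ranking" regardless of m and T. Genes of a set absent from the matrix
are intersected away; no absent-gene penalty is applied. The default
q = 0.05 follows the convention of rank-based single-cell scoring;
larger q makes scores smoother but less specific. Scoring a single set
with an empty universe intersection is an error; batch scoring drops
such sets with a warning instead, because database-scale collections
routinely contain sets irrelevant to the measured genes. Database-wide
runs are expected to be size-filtered first (the CLI defaults to 10–500
genes per set).

The vectorized implementation is checked against an independent
brute-force oracle (explicit per-cell sort and k-by-k curve
accumulation) to 1e-12 over randomized sets, cutoffs and tie rules.

## Gene-set and ontology handling

GMT, minimal GAF 2.x (symbol/qualifier/term/aspect columns; rows with a
NOT qualifier dropped; evidence codes not filtered) and a minimal OBO
subset ([Term], id, name, is_a, is_obsolete) are supported, plus a plain
TSV edge list as a neutral alternative for hierarchies that are not
distributed as OBO. Only `is_a` edges are honored; `part_of` and other
relationship types are ignored. Pruning removes obsolete terms together
with their incident edges and does **not** reattach orphaned children to
grandparents — children of a pruned term simply become roots. This is
the conservative reading of removing terms from the relational network;
reattachment would fabricate relations no source asserted. Descendant
and ancestor closures are computed on the pruned DAG and cached.
Collection filtering composes conjunctively: gene-count bounds, subtree
membership under given root terms (roots included), and end-level-only
(terms with no children in the pruned graph).

## Pathway-space pipeline

Stages: per-cell library-size normalization to 10,000 counts + log1p
(irrelevant to the rank-based scores, but it keeps the expression-space
comparison arm conventional) → AUCell scoring → per-set z-scoring
(sample sd; rows with sd below 1e-12·(|mean|+1) set to 0; clipped at
±10) → PCA (full SVD, cells as observations; requested components are
lowered with a warning when fewer sets are available) → clustering →
optional seeded UMAP. Whether scores should be standardized before PCA
is genuinely open; z-scoring per set is the default because raw AUCell
score levels vary with set size, which would otherwise dominate the
principal components.

Clustering offers Leiden (RBConfiguration partition at resolution 0.8 on
an unweighted symmetric k-NN graph, k = 20, seeded) as the
field-standard default and seeded k-means as the exactly-testable path.
Leiden at a fixed resolution deliberately over-partitions tight planted
blobs — useful for the annotation workflow, which assumes
over-clustering — so quantitative recovery checks against planted types
(the acceptance analyses) use k-means with k set to the number of
planted types; Leiden is tested for determinism and contract behavior.

Every stage records a SHA-256 content hash of its inputs. With a cache
attached, a rerun skips stages whose input hashes are unchanged and
re-executes everything downstream of any change.

## Cluster annotation

Marker signatures are scored per cell, averaged per cluster, and each
signature row is z-scored across clusters; each cluster is assigned the
signature with the highest z (ties broken lexicographically; an optional
minimum z withholds assignment). This reproduces the signatures ×
clusters heatmap convention and is scale-free. A consequence worth
knowing: because z-scoring is scale-free, a signature whose cluster
means are *flat but noisy* (e.g., a random gene set with no biological
structure) is amplified to the same z range as a genuine signature, and
with k clusters a signature enriched in j of them cannot exceed
z = (1−j/k)/√(j/k·(1−j/k)·k/(k−1)). Screening candidate signatures for
near-constant raw means (or using `min_z`) is advisable with noisy
custom collections; the synthetic benchmark's distractors are therefore
modeled as signatures of related-but-absent cell types (structured, but
not specific to any planted type), which is also the realistic failure
mode for curated marker databases.

## Group statistics

Per-feature group summaries: mean, median, z-score of group means
(sample sd, degenerate rows → 0, rows sum to 0 within 1e-9), one-vs-rest
log2 fold change with pseudocount 1 on group means (standard
stabilization), one-vs-rest Welch t, and proportion of cells strictly
above a threshold. Waterfall ranking between two groups sorts by the
chosen contrast and flags the top 20 features by |metric| for labeling
(ties by feature id; clamped to the feature count). Two-group
significance uses the rank-sum test (Mann–Whitney normal approximation
with continuity and tie correction; single-cell convention) or Welch's
t; features constant across both groups get p = 1 with a warning. Stars
follow the four-tier convention (0.05, 0.01, 0.001, 0.0001). No
multiple-testing correction is applied by default.

The GSEA running score follows the Broad formulation: walking the
descending-ordered statistic, a set member at position i adds
|s_i|^p / Σ_hits |s|^p (p = 1 by default) and a non-member subtracts
1/(G−m); the ES is the signed maximum deviation and the leading edge
collects members up to (ES > 0) or after (ES < 0) the extremum. The
curve starts and ends at 0 by construction. The p-value is a two-sample
Kolmogorov–Smirnov test of member vs non-member rank positions
(asymptotic), not a phenotype permutation — fast, deterministic, and
appropriate for the positional question the plot answers.

## Colors

Palettes are generated by seeded k-means over a dense sample of a
perceptual constraint box (uniform in LCh over the family's hue,
lightness and chroma ranges; out-of-gamut samples rejected by a
round-trip test through sRGB). Centroids are snapped to the nearest
in-box sample — a centroid of an annular or wrapped hue region can
otherwise fall outside the box — so constraint satisfaction is exact by
construction, at the cost that n = 1 returns the in-box sample nearest
the box centroid rather than the raw centroid. Output is hue-sorted.
Seven families are registered: `default` and `light` span the full hue
circle at mid and high lightness; `red`, `yellow`, `green`, `blue` and
`purple` confine hue to their region. Distinctness is validated against
a Monte-Carlo baseline (minimum pairwise CIELAB ΔE of the optimized
palette vs the 95th percentile over random same-box draws).

RGB blending maps up to three scaled features (99th-percentile clip,
then min-max to [0,1]) directly onto R, G, B: black = no signal. RYB
blending interpolates trilinearly over 8 corner colors (white at the
origin, tuned red/yellow/blue primaries, their pairwise mixes, and a
near-black at full saturation): white = no signal, deeper = more. The
shipped corners darken yellow toward gold and lighten blue toward azure
— the pure primaries render too light and too dark respectively — and
were chosen so that increasing any single RYB coordinate never raises
CIELAB L* (checked on a 6³ grid at config load; corner tables violating
this monotone-deepening contract are rejected).

## Synthetic data

The generator emulates the structure pathway-level clustering exploits,
not the full complexity of real data. Defaults: 2,000 cells × 2,000
genes, 3 cell types, 6 disjoint 50-gene programs (2 per type, assigned
round-robin), negative-binomial counts (mean 0.5, dispersion 2;
program genes of a cell's active programs ×4), 30% extra dropout zeros.
The optional batch effect multiplies the means of a random 30% of
*non-program* genes by 2 in every batch beyond the first — deliberately
confined to non-program genes so that the contrast "gene-space
clustering is confounded by batch, pathway-space is not" exists as a
testable inequality rather than an anecdote. Marker signatures take the
first half of each of a type's program gene blocks; distractor
signatures take the second halves from programs of two different types.

Not modeled: library-size heterogeneity, gene–gene correlation within
programs beyond shared means, doublets, UMI noise, per-cell detection
efficiency. Passing recovery tests on this generator demonstrates the
pipeline's correctness and its batch-damping mechanism, not performance
on real tissue.

The toy ontology builds balanced binary trees (one per named branch,
2^depth − 1 terms each) with gene sets attached at the leaves and an
optional fraction of internal terms flagged obsolete for pruning tests.

## Problem sizes and determinism

The automated analyses run at 2,000 cells (batch-robustness contrast and
default-fixture annotation), 500 cells × 20 seeds (annotation
stability), 2,000 features (test calibration), and ontologies up to ~170
terms — sizes chosen so the full suite completes in about a minute on a
laptop core while keeping every estimate's Monte-Carlo error well inside
the margins being asserted. All randomness flows from explicit seeds;
identical inputs and seeds give bit-identical scores and labels, and
PCs/embeddings reproducible to floating-point tolerance.

## Known limitations

- AUCell scores are sensitive to the number of genes detected per cell;
  strong nGene differences between samples can masquerade as pathway
  differences. No correction is applied.
- The KS-based GSEA p-value tests rank positions only; it does not
  account for inter-gene correlation and is not a phenotype-permutation
  FDR.
- Score binarization (on/off thresholding of AUCell scores) is not
  implemented.
- Batch integration beyond the structural robustness of pathway scores
  (e.g., Harmony-style correction) is out of scope; the pipeline has no
  integration stage.
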