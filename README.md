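# pathcell

Pathway-level analysis for single-cell RNA-seq: rank-based gene-set
enrichment scoring (AUCell), ontology-aware gene-set management,
clustering and embedding of cells in pathway-score space, marker-signature
cluster annotation, group statistics for the usual visualizations, and
professional color tooling — all exercisable offline on synthetic data
with planted structure.

## Who this is for

Analysts who want to interpret single-cell heterogeneity through curated
gene programs (GO/Reactome-style pathways, cell-type marker signatures,
TF regulons) rather than through individual genes. Clustering cells on a
pathway-score matrix instead of the expression matrix damps gene-level
fluctuations and batch effects confined to genes outside the curated
programs, and signature enrichment per cluster turns annotation into a
sortable table instead of a marker-by-marker hunt.

## The core score

For each cell, genes are ranked by decreasing expression (rank 1 =
highest). For a gene set with *m* members present among the *G* genes of
the matrix, with rank cutoff *T* = max(1, ⌊*q·G*⌋) (top fraction *q*,
default 0.05), the recovery curve *R(k)* counts set members among the
top-*k* ranked genes. The enrichment score is the normalized area under
the curve's initial segment:

    A     = Σ_{k=1..T} R(k)
    A_max = Σ_{k=1..T} min(k, m)
    score = A / A_max  ∈ [0, 1]

1 means the set fully occupies the top of the cell's ranking; 0 means no
member enters the top fraction. The score is invariant to any monotone
per-cell transform of expression, so normalization choices do not affect
it. A brute-force oracle (`oracle_score_set`, an explicit k-loop sharing
no code with the vectorized path) verifies the implementation exactly.

Downstream, the gene sets × cells score matrix is standardized per set,
reduced by PCA, clustered (Leiden on a k-NN graph, or k-means), and
optionally embedded with UMAP. Cluster annotation averages signature
scores per cluster, z-scores each signature across clusters, and labels
each cluster with its top signature.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from pathcell import (AucellParams, PipelineConfig, SyntheticSpec,
                      annotate_clusters, cluster_signature_matrix,
                      run_pathway_pipeline, score_collection,
                      simulate_dataset)

bundle = simulate_dataset(SyntheticSpec(n_cells=1000, seed=1))
config = PipelineConfig(cluster_method="kmeans", k=3, embed="none")
result = run_pathway_pipeline(bundle.expr, bundle.program_sets, config,
                              AucellParams(seed=0))
print("ARI vs planted types:",
      round(adjusted_rand_score(bundle.cell_types, result.labels), 3))

scores = score_collection(bundle.expr, bundle.marker_sets, AucellParams(seed=0))
ann = annotate_clusters(cluster_signature_matrix(scores, result.labels))
for cluster, best in sorted(ann.assigned.items()):
    print(f"cluster {cluster}: {best} (z = {ann.ranking[cluster][0][1]:.2f})")
```

Output:

```
ARI vs planted types: 1.0
cluster 0: type1_markers (z = 1.15)
cluster 1: type2_markers (z = 1.15)
cluster 2: type0_markers (z = 1.15)
```

The generator plants 3 cell types, each activating 2 of 6 disjoint
50-gene programs in negative-binomial counts with dropout. Clustering
the AUCell scores of the 6 program sets recovers the planted types
exactly (ARI 1.0), and each cluster's top-ranked marker signature is the
planted type's own (z = 1.15 is the maximum attainable when one of three
clusters is enriched: (1−⅓)/√(1/3)).

The same flows are available from the shell:

```sh
pathcell simulate --out sim/ --seed 1 --cells 1000
pathcell cluster --expr sim/counts.mtx --features sim/counts.features.tsv \
    --barcodes sim/counts.barcodes.tsv --sets sim/programs.gmt \
    --out run/ --cluster-method kmeans --k 3 --no-embed
pathcell palette --family default -n 5
# -> #C8655C #A07B34 #548A50 #6885C6 #B05F9A
```

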