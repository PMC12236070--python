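"""Semi-automated cluster annotation from cell-type marker signatures.

Cells are scored against a marker-signature collection (one set per
candidate cell type) with AUCell; signature scores are averaged per
cluster and z-scored across clusters, and each cluster is labeled with
its top signature. This reproduces the familiar signatures x clusters
heatmap workflow: the z-row of a signature shows where it is enriched,
and reading the argmax down each cluster column suggests the label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aucell import ScoreMatrix
from .errors import DataError, UsageError
from .group_stats import GroupStats, group_metric

__all__ = ["AnnotationResult", "cluster_signature_matrix", "annotate_clusters"]


@dataclass
class AnnotationResult:
    """Ranked signatures per cluster plus the assigned label (or None)."""

    ranking: dict[str, list[tuple[str, float, float]]]  # cluster -> [(sig, z, mean)]
    assigned: dict[str, str | None]
    top_k: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cluster, entries in self.ranking.items():
            for rank, (sig, z, mean) in enumerate(entries, start=1):
                rows.append({
                    "cluster": cluster, "rank": rank, "signature": sig,
                    "z": z, "mean": mean,
                    "assigned": int(rank == 1 and self.assigned[cluster] == sig),
                })
        return pd.DataFrame(rows)


def cluster_signature_matrix(scores: ScoreMatrix, labels) -> GroupStats:
    """Signatures x clusters matrix: cluster means of AUCell scores,
    z-scored across clusters (sample sd, zero-sd rows -> 0)."""
    labels = np.asarray(labels)
    if len(labels) != len(scores.cell_ids):
        raise DataError("one label per cell required")
    clusters = pd.unique(labels)
    if len(clusters) < 2:
        raise DataError("need >= 2 clusters to compare signatures across clusters")
    df = scores.to_frame()
    means = group_metric(df, labels, "mean")
    z = group_metric(df, labels, "zscore")
    z.params["means"] = means.values
    return z


def annotate_clusters(stats: GroupStats, top_k: int = 5,
                      min_z: float | None = None) -> AnnotationResult:
    """Rank signatures per cluster by z and assign the top one.

    The label is withheld when ``min_z`` is given and no signature
    reaches it. Ties are broken by signature id (lexicographic) for
    determinism.
    """
    if top_k < 1:
        raise UsageError("top_k must be >= 1")
    if stats.metric != "zscore":
        raise UsageError("annotate_clusters expects a z-scored signature matrix")
    means = stats.params.get("means")
    ranking: dict[str, list[tuple[str, float, float]]] = {}
    assigned: dict[str, str | None] = {}
    for cluster in stats.values.columns:
        col = stats.values[cluster]
        order = sorted(col.index, key=lambda s: (-col[s], str(s)))
        top = order[: top_k]
        ranking[str(cluster)] = [
            (
                str(s),
                float(col[s]),
                float(means.loc[s, cluster]) if means is not None else float("nan"),
            )
            for s in top
        ]
        best = top[0]
        if min_z is not None and col[best] < min_z:
            assigned[str(cluster)] = None
        else:
            assigned[str(cluster)] = str(best)
    return AnnotationResult(ranking=ranking, assigned=assigned, top_k=top_k)
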