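"""Dimensionality reduction and clustering in pathway-score space.

Instead of clustering cells on gene expression, cells are scored against
a gene-set collection with AUCell and the sets x cells score matrix
becomes the feature space: standardize per set, PCA, k-NN graph, Leiden
(or k-means), optional UMAP. Because pathway scores aggregate over
curated gene programs, fluctuations of individual genes — including
batch effects confined to genes outside the programs — are damped, which
is the point of the approach.

Every stage records a content hash of its inputs; re-running with an
attached :class:`PipelineCache` skips stages whose input hashes are
unchanged and re-executes everything downstream of a change.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .aucell import AucellParams, ScoreMatrix, score_collection
from .errors import DataError, UsageError
from .geneset_db import GeneSetCollection
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineCache",
    "PathwaySpaceResult",
    "normalize_expression",
    "standardize_scores",
    "cluster_cells",
    "run_pathway_pipeline",
    "run_expression_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the pathway-space pipeline.

    normalize: ``libsize_log1p`` scales each cell to 10,000 counts and
        applies log1p (rank-based scoring is unaffected; this matters for
        the expression-space comparison arm), or ``none``.
    score_standardize: ``zscore_per_set`` (sample sd, zero-sd rows -> 0,
        clipped at ±zclip) or ``none``.
    cluster_method: ``leiden`` (k-NN graph + Leiden at ``resolution``) or
        ``kmeans`` (``k`` centers; the exactly-testable path).
    embed: ``umap`` or ``none``.
    """

    normalize: str = "libsize_log1p"
    score_standardize: str = "zscore_per_set"
    zclip: float = 10.0
    n_pcs: int = 50
    k_neighbors: int = 20
    cluster_method: str = "leiden"
    resolution: float = 0.8
    k: int = 8
    embed: str = "umap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalize not in ("libsize_log1p", "none"):
            raise UsageError(f"unknown normalize {self.normalize!r}")
        if self.score_standardize not in ("zscore_per_set", "none"):
            raise UsageError(f"unknown score_standardize {self.score_standardize!r}")
        if self.n_pcs < 2:
            raise UsageError("n_pcs must be >= 2")
        if self.k_neighbors < 2:
            raise UsageError("k_neighbors must be >= 2")
        if self.cluster_method not in ("leiden", "kmeans"):
            raise UsageError(f"unknown cluster_method {self.cluster_method!r}")
        if self.embed not in ("umap", "none"):
            raise UsageError(f"unknown embed {self.embed!r}")


@dataclass
class PathwaySpaceResult:
    scores: ScoreMatrix | None
    pcs: np.ndarray  # cells x n_pcs
    labels: np.ndarray  # per-cell cluster ids (int)
    embedding: np.ndarray | None
    stage_hashes: dict[str, str]
    stages_skipped: list[str] = field(default_factory=list)


class PipelineCache:
    """In-memory stage cache keyed by content hash of stage inputs."""

    def __init__(self) -> None:
        self._store: dict[str, tuple[str, object]] = {}

    def get(self, stage: str, input_hash: str):
        entry = self._store.get(stage)
        if entry is not None and entry[0] == input_hash:
            return entry[1]
        return None

    def put(self, stage: str, input_hash: str, payload) -> None:
        self._store[stage] = (input_hash, payload)


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
            h.update(str(p.shape).encode())
        elif isinstance(p, bytes):
            h.update(p)
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()


def normalize_expression(expr: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Per-cell library-size scaling to 10,000 followed by log1p."""
    if method == "none":
        return expr
    totals = expr.values.sum(axis=0)
    totals = np.where(totals == 0, 1.0, totals)
    X = np.log1p(expr.values / totals * 1e4)
    return ExpressionMatrix(X, expr.gene_ids, expr.cell_ids)


def standardize_scores(scores: np.ndarray, method: str = "zscore_per_set",
                       zclip: float = 10.0) -> np.ndarray:
    """Row-wise z-scoring (ddof=1) with clipping; ``none`` is passthrough."""
    scores = np.asarray(scores, dtype=float)
    if method == "none":
        return scores
    if scores.shape[1] < 2:
        raise DataError("z-scoring requires >= 2 cells")
    mu = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, ddof=1, keepdims=True)
    # constant rows: sd may be ~1e-17 rather than exactly 0
    degenerate = sd <= 1e-12 * (np.abs(mu) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (scores - mu) / sd
    z[np.broadcast_to(degenerate, z.shape)] = 0.0
    return np.clip(z, -zclip, zclip)


def _knn_graph(pcs: np.ndarray, k: int):
    from sklearn.neighbors import NearestNeighbors
    import igraph as ig

    nn = NearestNeighbors(n_neighbors=min(k + 1, len(pcs))).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=len(pcs), edges=sorted(edges))
    return g


def cluster_cells(pcs: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Cluster cells in PC space by Leiden or seeded k-means."""
    pcs = np.asarray(pcs, dtype=float)
    if not np.all(np.isfinite(pcs)):
        raise DataError("non-finite values in PC matrix")
    if len(pcs) > 1 and np.allclose(pcs, pcs[0]):
        warnings.warn("all cells identical in PC space; single cluster", stacklevel=2)
        return np.zeros(len(pcs), dtype=int)
    if config.cluster_method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=config.k, random_state=config.seed, n_init=10)
        return km.fit_predict(pcs).astype(int)
    import leidenalg

    g = _knn_graph(pcs, config.k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=config.resolution,
        seed=config.seed,
    )
    return np.asarray(part.membership, dtype=int)


def _pca(features_cells: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    from sklearn.decomposition import PCA

    n_feat, n_cells = features_cells.shape
    n_pcs_eff = min(n_pcs, n_feat - 1 if n_feat > 1 else 1, n_cells - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"n_pcs lowered to {n_pcs_eff} (only {n_feat} features)",
                      stacklevel=2)
    p = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    return p.fit_transform(features_cells.T)


def _embed_umap(pcs: np.ndarray, config: PipelineConfig) -> np.ndarray:
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=config.k_neighbors, random_state=config.seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(pcs), dtype=float)


def _run_stages(feature_matrix: np.ndarray, config: PipelineConfig,
                upstream_hash: str, scores: ScoreMatrix | None,
                cache: PipelineCache | None,
                stage_hashes: dict[str, str], skipped: list[str]) -> PathwaySpaceResult:
    if feature_matrix.shape[1] < config.k_neighbors:
        raise DataError(
            f"{feature_matrix.shape[1]} cells is fewer than k_neighbors={config.k_neighbors}"
        )

    def stage(name: str, input_hash: str, fn):
        stage_hashes[name] = input_hash
        if cache is not None:
            hit = cache.get(name, input_hash)
            if hit is not None:
                skipped.append(name)
                logger.info("stage %s skipped (input hash unchanged)", name)
                return hit
        out = fn()
        if cache is not None:
            cache.put(name, input_hash, out)
        return out

    h_std = _hash(upstream_hash, config.score_standardize, config.zclip)
    standardized = stage(
        "standardize", h_std,
        lambda: standardize_scores(feature_matrix, config.score_standardize, config.zclip),
    )
    h_pca = _hash(h_std, config.n_pcs, config.seed, "pca")
    pcs = stage("pca", h_pca, lambda: _pca(standardized, config.n_pcs, config.seed))
    h_clu = _hash(h_pca, config.cluster_method, config.resolution, config.k,
                  config.k_neighbors, config.seed)
    labels = stage("cluster", h_clu, lambda: cluster_cells(pcs, config))
    embedding = None
    if config.embed == "umap":
        h_emb = _hash(h_pca, "umap", config.k_neighbors, config.seed)
        embedding = stage("embed", h_emb, lambda: _embed_umap(pcs, config))
    return PathwaySpaceResult(
        scores=scores, pcs=pcs, labels=labels, embedding=embedding,
        stage_hashes=dict(stage_hashes), stages_skipped=list(skipped),
    )


def run_pathway_pipeline(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    config: PipelineConfig | None = None,
    aucell: AucellParams | None = None,
    cache: PipelineCache | None = None,
) -> PathwaySpaceResult:
    """normalize -> AUCell -> standardize -> PCA -> cluster -> embed."""
    config = config or PipelineConfig()
    aucell = aucell or AucellParams()
    stage_hashes: dict[str, str] = {}
    skipped: list[str] = []

    def stage(name, input_hash, fn):
        stage_hashes[name] = input_hash
        if cache is not None:
            hit = cache.get(name, input_hash)
            if hit is not None:
                skipped.append(name)
                logger.info("stage %s skipped (input hash unchanged)", name)
                return hit
        out = fn()
        if cache is not None:
            cache.put(name, input_hash, out)
        return out

    h_in = _hash(expr.values, expr.gene_ids, expr.cell_ids)
    h_norm = _hash(h_in, config.normalize)
    normalized = stage("normalize", h_norm,
                       lambda: normalize_expression(expr, config.normalize))
    coll_repr = {i: gs.genes for i, gs in collection.sets.items()}
    h_score = _hash(h_norm, coll_repr, asdict(aucell))
    scores = stage("score", h_score,
                   lambda: score_collection(normalized, collection, aucell))
    return _run_stages(scores.scores, config, h_score, scores, cache,
                       stage_hashes, skipped)


def run_expression_pipeline(
    expr: ExpressionMatrix,
    config: PipelineConfig | None = None,
    cache: PipelineCache | None = None,
) -> PathwaySpaceResult:
    """Same pipeline with normalized expression as the feature space.

    The comparison arm for pathway- vs gene-space clustering: stages and
    parameters are identical, only the scoring stage is replaced by the
    (normalized) gene x cell matrix itself.
    """
    config = config or PipelineConfig()
    stage_hashes: dict[str, str] = {}
    skipped: list[str] = []
    h_in = _hash(expr.values, expr.gene_ids, expr.cell_ids)
    h_norm = _hash(h_in, config.normalize)
    normalized = normalize_expression(expr, config.normalize)
    stage_hashes["normalize"] = h_norm
    return _run_stages(normalized.values, config, h_norm, None, cache,
                       stage_hashes, skipped)
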