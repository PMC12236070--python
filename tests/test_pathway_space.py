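"""Pathway-space pipeline: standardization, clustering, caching, recovery."""
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pathcell import (AucellParams, DataError, PipelineCache, PipelineConfig,
                      SyntheticSpec, cluster_cells, run_expression_pipeline,
                      run_pathway_pipeline, simulate_dataset,
                      standardize_scores)

KMEANS3 = dict(cluster_method="kmeans", k=3, embed="none", k_neighbors=10)


def test_standardize_zero_sd_row_maps_to_zero():
    out = standardize_scores(np.array([[0.2, 0.2, 0.2]]))
    np.testing.assert_array_equal(out, [[0.0, 0.0, 0.0]])


def test_standardize_sample_sd():
    out = standardize_scores(np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])


def test_standardize_clips_and_rejects_single_cell():
    rng = np.random.default_rng(0)
    out = standardize_scores(rng.normal(size=(5, 50)), zclip=1.5)
    assert np.abs(out).max() <= 1.5
    with pytest.raises(DataError):
        standardize_scores(np.ones((3, 1)))


def test_kmeans_separated_blobs_exact_recovery():
    rng = np.random.default_rng(7)
    pcs = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(10, 1, (100, 4))])
    truth = np.array([0] * 100 + [1] * 100)
    labels = cluster_cells(pcs, PipelineConfig(cluster_method="kmeans", k=2,
                                               embed="none"))
    assert adjusted_rand_score(truth, labels) == 1.0


def test_identical_rows_single_cluster_with_warning():
    with pytest.warns(UserWarning, match="single cluster"):
        labels = cluster_cells(np.ones((30, 3)), PipelineConfig(embed="none"))
    assert set(labels.tolist()) == {0}


def test_clustering_deterministic_given_seed():
    rng = np.random.default_rng(1)
    pcs = rng.normal(size=(120, 5))
    for method in ("kmeans", "leiden"):
        cfg = PipelineConfig(cluster_method=method, k=4, resolution=0.8,
                             embed="none", k_neighbors=10, seed=5)
        a = cluster_cells(pcs, cfg)
        b = cluster_cells(pcs, cfg)
        np.testing.assert_array_equal(a, b)


def test_pipeline_recovers_planted_types(small_bundle):
    cfg = PipelineConfig(**KMEANS3)
    res = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                               cfg, AucellParams(seed=0))
    ari = adjusted_rand_score(small_bundle.cell_types, res.labels)
    assert ari >= 0.8


def test_null_structure_gives_near_zero_ari():
    spec = SyntheticSpec(n_cells=400, n_genes=800, program_effect=1.0,
                         dropout=0.0, seed=11)
    b = simulate_dataset(spec)
    res = run_pathway_pipeline(b.expr, b.program_sets,
                               PipelineConfig(**KMEANS3), AucellParams(seed=0))
    assert adjusted_rand_score(b.cell_types, res.labels) <= 0.05


def test_embed_none_omits_embedding(small_bundle):
    res = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                               PipelineConfig(**KMEANS3), AucellParams(seed=0))
    assert res.embedding is None
    assert set(res.stage_hashes) == {"normalize", "score", "standardize",
                                     "pca", "cluster"}


def test_cache_skips_identical_rerun_and_invalidates_on_change(small_bundle):
    cache = PipelineCache()
    cfg = PipelineConfig(**KMEANS3)
    params = AucellParams(seed=0)
    first = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                                 cfg, params, cache=cache)
    assert first.stages_skipped == []
    second = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                                  cfg, params, cache=cache)
    assert set(second.stages_skipped) == {"normalize", "score", "standardize",
                                          "pca", "cluster"}
    np.testing.assert_array_equal(first.labels, second.labels)
    np.testing.assert_array_equal(first.pcs, second.pcs)
    assert first.stage_hashes == second.stage_hashes
    # perturb the input: every downstream stage re-executes
    from pathcell import ExpressionMatrix
    mutated = ExpressionMatrix(small_bundle.expr.values + 1.0,
                               small_bundle.expr.gene_ids,
                               small_bundle.expr.cell_ids)
    third = run_pathway_pipeline(mutated, small_bundle.program_sets, cfg,
                                 params, cache=cache)
    assert third.stages_skipped == []
    assert third.stage_hashes["score"] != second.stage_hashes["score"]


def test_pipeline_determinism(small_bundle):
    cfg = PipelineConfig(**KMEANS3)
    a = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                             cfg, AucellParams(seed=0))
    b = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                             cfg, AucellParams(seed=0))
    np.testing.assert_allclose(a.pcs, b.pcs, atol=1e-8)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_too_few_cells_for_neighbors_errors(small_bundle):
    from pathcell import ExpressionMatrix
    tiny = ExpressionMatrix(small_bundle.expr.values[:, :5],
                            small_bundle.expr.gene_ids,
                            small_bundle.expr.cell_ids[:5])
    with pytest.raises(DataError, match="k_neighbors"):
        run_pathway_pipeline(tiny, small_bundle.program_sets,
                             PipelineConfig(**KMEANS3), AucellParams(seed=0))


def test_batch_robustness_inequality(small_bundle):
    """Batch shift on non-program genes: pathway-space clustering is at
    least as faithful to the planted types as gene-space clustering."""
    spec = SyntheticSpec(n_cells=400, n_genes=800, batch="nonprogram_shift",
                         seed=3)
    b = simulate_dataset(spec)
    cfg = PipelineConfig(**KMEANS3)
    path = run_pathway_pipeline(b.expr, b.program_sets, cfg, AucellParams(seed=0))
    gene = run_expression_pipeline(b.expr, cfg)
    ari_path = adjusted_rand_score(b.cell_types, path.labels)
    ari_gene = adjusted_rand_score(b.cell_types, gene.labels)
    assert ari_path >= ari_gene
    assert ari_path >= 0.8


def test_umap_embedding_shape_and_determinism(small_bundle):
    cfg = PipelineConfig(cluster_method="kmeans", k=3, embed="umap",
                         k_neighbors=10)
    a = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                             cfg, AucellParams(seed=0))
    assert a.embedding.shape == (small_bundle.expr.n_cells, 2)
    b = run_pathway_pipeline(small_bundle.expr, small_bundle.program_sets,
                             cfg, AucellParams(seed=0))
    np.testing.assert_allclose(a.embedding, b.embedding, atol=1e-6)
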