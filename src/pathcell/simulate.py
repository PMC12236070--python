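"""Synthetic single-cell data with planted structure.

The generator emulates the structure that pathway-level clustering
exploits: disjoint gene "programs" (pathway-sized gene blocks), cell
types defined by which programs they activate, negative-binomial counts
with extra dropout zeros, and an optional batch effect that perturbs
only genes OUTSIDE the programs. That last restriction is deliberate:
it reproduces, as a testable contrast, the situation where gene-space
clustering is confounded by batch while pathway scores — computed over
program genes only — are not.

Also provides a toy ontology (balanced trees of named branches with
leaf-attached gene sets and optional obsolete terms) for exercising
hierarchy filtering.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DataError, UsageError
from .geneset_db import GeneSet, GeneSetCollection, OntologyGraph
from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "SimulatedBundle", "simulate_dataset", "simulate_ontology"]

_BRANCH_NAMES = [
    "immune", "metabolism", "signaling", "development", "adhesion",
    "transport", "stress", "cell cycle",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic expression generator.

    Counts are negative binomial with mean ``nb_mean`` and dispersion
    ``nb_dispersion`` (var = mu + mu^2/dispersion); genes of a cell's
    active programs have their mean multiplied by ``program_effect``.
    ``dropout`` injects extra zeros uniformly. ``batch="nonprogram_shift"``
    multiplies the means of a random fraction of non-program genes by
    ``batch_shift`` in every batch but the first.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_types: int = 3
    n_program_sets: int = 6
    genes_per_program: int = 50
    program_effect: float = 4.0
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    dropout: float = 0.3
    batch: str = "none"
    batch_shift: float = 2.0
    n_batches: int = 2
    batch_affected_frac: float = 0.3
    n_distractor_signatures: int = 9
    markers_per_signature: int = 50
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_program_sets * self.genes_per_program > self.n_genes:
            raise DataError("programs exceed the gene count")
        if self.n_program_sets < self.n_types:
            raise UsageError("need at least one program per type")
        if self.batch not in ("none", "nonprogram_shift"):
            raise UsageError(f"unknown batch mode {self.batch!r}")
        if min(self.program_effect, self.nb_mean, self.nb_dispersion) <= 0:
            raise UsageError("effects, means and dispersions must be positive")
        if not (0 <= self.dropout < 1):
            raise UsageError("dropout must be in [0, 1)")


@dataclass
class SimulatedBundle:
    expr: ExpressionMatrix  # raw counts
    cell_types: np.ndarray  # per-cell type index
    batches: np.ndarray  # per-cell batch index
    program_sets: GeneSetCollection
    marker_sets: GeneSetCollection
    truth: dict


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_dataset(spec: SyntheticSpec | None = None) -> SimulatedBundle:
    """Draw one dataset bundle, fully determined by ``spec.seed``."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    G, C = spec.n_genes, spec.n_cells
    gene_ids = [f"g{i:05d}" for i in range(G)]
    cell_ids = [f"c{i:05d}" for i in range(C)]

    # disjoint program blocks at the front of the gene list
    programs = [
        list(range(p * spec.genes_per_program, (p + 1) * spec.genes_per_program))
        for p in range(spec.n_program_sets)
    ]
    nonprogram = list(range(spec.n_program_sets * spec.genes_per_program, G))
    # round-robin program assignment: every type gets >= 1 program
    type_programs: dict[int, list[int]] = {t: [] for t in range(spec.n_types)}
    for p in range(spec.n_program_sets):
        type_programs[p % spec.n_types].append(p)

    cell_types = rng.integers(0, spec.n_types, size=C)
    batches = (
        rng.integers(0, spec.n_batches, size=C)
        if spec.batch != "none"
        else np.zeros(C, dtype=int)
    )

    means = np.full((G, C), spec.nb_mean)
    for t in range(spec.n_types):
        cols = cell_types == t
        for p in type_programs[t]:
            means[np.ix_(programs[p], cols)] *= spec.program_effect
    if spec.batch == "nonprogram_shift":
        n_aff = int(round(spec.batch_affected_frac * len(nonprogram)))
        for b in range(1, spec.n_batches):
            affected = rng.choice(nonprogram, size=n_aff, replace=False)
            means[np.ix_(affected, batches == b)] *= spec.batch_shift

    counts = _nb_draw(rng, means, spec.nb_dispersion).astype(float)
    if spec.dropout > 0:
        counts *= rng.random((G, C)) >= spec.dropout

    program_sets = GeneSetCollection(source="synthetic programs")
    for p, idx in enumerate(programs):
        program_sets.add(GeneSet(
            id=f"program_{p}", name=f"synthetic program {p}",
            genes=[gene_ids[i] for i in idx],
        ))

    marker_sets = GeneSetCollection(source="synthetic markers")
    signature_types: dict[str, int | None] = {}
    for t in range(spec.n_types):
        per_program = max(1, spec.markers_per_signature // max(1, len(type_programs[t])))
        genes: list[str] = []
        for p in type_programs[t]:
            genes.extend(gene_ids[i] for i in programs[p][:per_program])
        sid = f"type{t}_markers"
        marker_sets.add(GeneSet(id=sid, name=f"cell type {t} markers", genes=genes))
        signature_types[sid] = t
    # Distractors emulate signatures of related-but-absent cell types:
    # genes drawn from programs of two DIFFERENT planted types, so the
    # signature varies across clusters without being specific to any one
    # type. (A flat pure-noise signature would be amplified by the
    # z-across-clusters ranking convention; see the methods note.)
    half = max(1, spec.markers_per_signature // 2)
    pairs = [(a, b) for a in range(spec.n_types) for b in range(spec.n_types) if a != b]
    for d in range(spec.n_distractor_signatures):
        t1, t2 = pairs[d % len(pairs)]
        p1 = type_programs[t1][d % len(type_programs[t1])]
        p2 = type_programs[t2][(d // 2) % len(type_programs[t2])]
        genes = [gene_ids[i] for i in programs[p1][-half:]]
        genes += [gene_ids[i] for i in programs[p2][-half:]]
        sid = f"distractor_{d}"
        marker_sets.add(GeneSet(id=sid, name=f"distractor signature {d}",
                                genes=genes))
        signature_types[sid] = None

    truth = {
        "cell_types": cell_types.tolist(),
        "batches": batches.tolist(),
        "type_programs": {str(t): ps for t, ps in type_programs.items()},
        "signature_types": {
            k: (int(v) if v is not None else None) for k, v in signature_types.items()
        },
        "seed": spec.seed,
    }
    expr = ExpressionMatrix(counts, gene_ids, cell_ids)
    return SimulatedBundle(expr, cell_types, batches, program_sets, marker_sets, truth)


def simulate_ontology(
    n_branches: int = 2,
    depth: int = 3,
    sets_per_leaf: int = 1,
    seed: int = 0,
    obsolete_fraction: float = 0.0,
    gene_universe: list[str] | None = None,
) -> tuple[OntologyGraph, GeneSetCollection]:
    """Balanced binary-tree ontology with leaf-attached gene sets.

    Each branch root expands into a complete binary tree of ``depth``
    levels (2^depth - 1 terms per branch). Leaf terms carry gene sets:
    the first set of a leaf reuses the leaf's own term id; extra sets
    (``sets_per_leaf > 1``) are added as child terms of the leaf so
    hierarchy filters remain total over set ids. ``obsolete_fraction``
    randomly flags non-root internal terms obsolete.
    """
    if n_branches < 2 or depth < 2:
        raise UsageError("need n_branches >= 2 and depth >= 2")
    if sets_per_leaf < 1:
        raise UsageError("sets_per_leaf must be >= 1")
    rng = np.random.default_rng(seed)
    if gene_universe is None:
        gene_universe = [f"g{i:05d}" for i in range(500)]
    g = nx.DiGraph()
    counter = itertools.count()
    collection = GeneSetCollection(source="synthetic ontology sets")
    internal_nonroot: list[str] = []

    def term_id() -> str:
        return f"SYN:{next(counter):04d}"

    def random_set(set_id: str, name: str) -> GeneSet:
        size = int(rng.integers(10, 31))
        genes = [gene_universe[i] for i in
                 sorted(rng.choice(len(gene_universe), size=size, replace=False))]
        return GeneSet(id=set_id, name=name, genes=genes)

    for b in range(n_branches):
        branch = _BRANCH_NAMES[b % len(_BRANCH_NAMES)]
        root = term_id()
        g.add_node(root, name=branch, obsolete=False)
        level = [root]
        for d in range(1, depth):
            nxt: list[str] = []
            for parent in level:
                for _ in range(2):
                    child = term_id()
                    g.add_node(child, name=f"{branch} subprocess {child[4:]}",
                               obsolete=False)
                    g.add_edge(parent, child)
                    nxt.append(child)
                    if d < depth - 1:
                        internal_nonroot.append(child)
            level = nxt
        for leaf in level:
            collection.add(random_set(leaf, g.nodes[leaf]["name"]))
            for extra in range(1, sets_per_leaf):
                child = f"{leaf}.s{extra}"
                g.add_node(child, name=f"{g.nodes[leaf]['name']} set {extra}",
                           obsolete=False)
                g.add_edge(leaf, child)
                collection.add(random_set(child, g.nodes[child]["name"]))

    if obsolete_fraction > 0 and internal_nonroot:
        n_obs = int(round(obsolete_fraction * len(internal_nonroot)))
        for t in rng.choice(internal_nonroot, size=n_obs, replace=False):
            g.nodes[t]["obsolete"] = True
    return OntologyGraph(g), collection
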