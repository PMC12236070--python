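"""Gene-set collections with an ontology hierarchy.

Gene sets arrive as GMT lines or GAF association rows; the term hierarchy
arrives as a minimal OBO file (``[Term]``/``id``/``name``/``is_a``/
``is_obsolete``) or a plain TSV edge list. After pruning obsolete terms
the graph supports descendant/ancestor closure queries, which power
subtree ("parent term") and end-level ("leaf pathway") filtering of a
collection. Only ``is_a`` relations are honored; ``part_of`` and other
``relationship:`` lines are ignored.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from .errors import DataError, ParseError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "OntologyGraph",
    "read_gmt",
    "read_gaf_minimal",
    "read_obo_minimal",
    "read_edge_list",
    "prune_and_index",
    "filter_collection",
    "resolve_names",
]


@dataclass
class GeneSet:
    """A named gene set: ordered, duplicate-free gene symbols."""

    id: str
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        deduped: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        self.genes = deduped
        if not self.genes:
            raise DataError(f"gene set {self.id!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Mapping of term id -> GeneSet with provenance metadata."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    source: str = ""
    species: str = "synthetic"

    def add(self, gs: GeneSet) -> None:
        if gs.id in self.sets:
            raise DataError(f"duplicate gene-set id {gs.id!r}")
        self.sets[gs.id] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def ids(self) -> list[str]:
        return list(self.sets)

    def subset(self, ids) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={i: self.sets[i] for i in ids}, source=self.source, species=self.species
        )


class OntologyGraph:
    """DAG of term parent->child relations with obsolete flags.

    Closure queries (``descendants``/``ancestors``) require
    :func:`prune_and_index` to have been run.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise DataError(f"ontology contains a cycle: {cycle}")
        self.graph = graph
        self._desc: dict[str, set[str]] | None = None
        self._anc: dict[str, set[str]] | None = None

    @property
    def terms(self) -> dict[str, tuple[str, bool]]:
        return {
            t: (d.get("name", t), bool(d.get("obsolete", False)))
            for t, d in self.graph.nodes(data=True)
        }

    @property
    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]

    @property
    def indexed(self) -> bool:
        return self._desc is not None

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name_of(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def is_obsolete(self, term: str) -> bool:
        return bool(self.graph.nodes[term].get("obsolete", False))

    def children(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def parents(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def is_leaf(self, term: str) -> bool:
        return self.graph.out_degree(term) == 0

    def descendants(self, term: str) -> set[str]:
        if self._desc is None:
            raise UsageError("closures not indexed; call prune_and_index first")
        if term not in self._desc:
            raise DataError(f"unknown term {term!r}")
        return set(self._desc[term])

    def ancestors(self, term: str) -> set[str]:
        if self._anc is None:
            raise UsageError("closures not indexed; call prune_and_index first")
        if term not in self._anc:
            raise DataError(f"unknown term {term!r}")
        return set(self._anc[term])


def read_gmt(path: str | Path, source: str = "", species: str = "synthetic") -> GeneSetCollection:
    """Parse a GMT file: ``id<TAB>description<TAB>gene1<TAB>gene2...``.

    The description field becomes the set name when non-empty, else the id.
    Duplicate genes within a line are dropped keeping first occurrence.
    """
    path = Path(path)
    coll = GeneSetCollection(source=source or str(path), species=species)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {set_id!r} has no genes")
            try:
                coll.add(GeneSet(id=set_id, name=desc or set_id, genes=genes))
            except DataError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return coll


def read_gaf_minimal(
    path: str | Path, aspect: str | None = None, species: str = "synthetic"
) -> GeneSetCollection:
    """Aggregate a minimal GAF 2.x association file into term -> genes.

    Uses column 3 (symbol), 4 (qualifier, rows containing NOT are dropped),
    5 (term id) and 9 (aspect, one of P/F/C). Lines starting with ``!``
    are comments.
    """
    if aspect is not None and aspect not in {"P", "F", "C"}:
        raise UsageError(f"aspect must be one of P, F, C; got {aspect!r}")
    path = Path(path)
    term_genes: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ParseError(
                    f"{path}:{lineno}: GAF row needs >=9 columns, got {len(cols)}"
                )
            symbol, qualifier, term, row_aspect = cols[2], cols[3], cols[4], cols[8]
            if not symbol or not term:
                raise ParseError(f"{path}:{lineno}: missing symbol or term id")
            if "NOT" in qualifier.split("|"):
                continue
            if aspect is not None and row_aspect != aspect:
                continue
            term_genes.setdefault(term, []).append(symbol)
    if not term_genes:
        raise DataError(f"{path}: no associations remain after filtering")
    coll = GeneSetCollection(source=str(path), species=species)
    for term, genes in term_genes.items():
        coll.add(GeneSet(id=term, name=term, genes=genes))
    return coll


def _build_graph(
    nodes: dict[str, dict], edges: list[tuple[str, str]], origin: str
) -> OntologyGraph:
    dangling = sorted(
        {t for pair in edges for t in pair if t not in nodes}
    )
    if dangling:
        raise DataError(f"{origin}: is_a references undeclared terms: {dangling}")
    g = nx.DiGraph()
    for term, attrs in nodes.items():
        g.add_node(term, **attrs)
    g.add_edges_from(edges)  # parent -> child
    return OntologyGraph(g)


def read_obo_minimal(path: str | Path) -> OntologyGraph:
    """Read a minimal OBO 1.2 subset into an ontology graph.

    Recognizes ``[Term]`` stanzas with ``id``, ``name``, ``is_a`` and
    ``is_obsolete: true``; all other tags (including ``relationship:``)
    are ignored. Edges run parent -> child.
    """
    path = Path(path)
    raw = obonet.read_obo(str(path), ignore_obsolete=False)
    nodes: dict[str, dict] = {}
    edges: list[tuple[str, str]] = []
    for term, data in raw.nodes(data=True):
        nodes[term] = {
            "name": data.get("name", term),
            "obsolete": data.get("is_obsolete", "false") in (True, "true"),
        }
    for child, parent, key in raw.edges(keys=True):
        if key != "is_a":
            continue
        edges.append((parent, child))
    # obonet drops is_a lines on obsolete terms and tolerates undeclared
    # targets; re-scan the raw text so the dangling/self-reference
    # contract is enforced on exactly what the file says.
    declared: set[str] = set()
    file_edges: list[tuple[str, str]] = []
    current: str | None = None
    in_term = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line == "[Term]":
            in_term, current = True, None
        elif line.startswith("["):
            in_term = False
        elif in_term and line.startswith("id:"):
            current = line[3:].strip()
            declared.add(current)
        elif in_term and line.startswith("is_a:") and current is not None:
            target = line[5:].strip().split("!")[0].strip()
            file_edges.append((target, current))
    dangling = sorted({p for p, c in file_edges if p not in declared})
    if dangling:
        raise DataError(f"{path}: is_a references undeclared terms: {dangling}")
    for term in declared:
        nodes.setdefault(term, {"name": term, "obsolete": False})
    return _build_graph(nodes, file_edges, str(path))


def read_edge_list(path: str | Path) -> OntologyGraph:
    """TSV edge-list loader: columns child_id, parent_id, name, obsolete{0,1}.

    A parent_id of ``-`` (or empty) declares a root term. Header row
    optional (detected by a ``child_id`` first field).
    """
    path = Path(path)
    nodes: dict[str, dict] = {}
    edges: list[tuple[str, str]] = []
    declared: set[str] = set()
    referenced: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0] == "child_id":
                continue
            if len(cols) < 4:
                raise ParseError(f"{path}:{lineno}: need 4 columns, got {len(cols)}")
            child, parent, name, obsolete = cols[0], cols[1], cols[2], cols[3]
            nodes[child] = {"name": name or child, "obsolete": obsolete == "1"}
            declared.add(child)
            if parent and parent != "-":
                edges.append((parent, child))
                referenced.add(parent)
    dangling = sorted(referenced - declared)
    if dangling:
        raise DataError(f"{path}: edges reference undeclared terms: {dangling}")
    return _build_graph(nodes, edges, str(path))


def prune_and_index(graph: OntologyGraph) -> OntologyGraph:
    """Drop obsolete terms (and their incident edges) and index closures.

    Children of a pruned term are NOT reattached to its parents; they
    simply become roots. Descendant/ancestor closures are computed over
    the pruned graph and cached for constant-time queries.
    """
    keep = [t for t in graph.graph.nodes if not graph.is_obsolete(t)]
    if not keep:
        raise DataError("pruning removed every term")
    pruned = OntologyGraph(graph.graph.subgraph(keep).copy())
    pruned._desc = {t: set(nx.descendants(pruned.graph, t)) for t in pruned.graph.nodes}
    pruned._anc = {t: set(nx.ancestors(pruned.graph, t)) for t in pruned.graph.nodes}
    return pruned


def filter_collection(
    collection: GeneSetCollection,
    graph: OntologyGraph | None = None,
    min_genes: int = 1,
    max_genes: int = 10**9,
    root_terms: list[str] | None = None,
    end_level_only: bool = False,
) -> GeneSetCollection:
    """Filter a collection by gene count and/or hierarchy position.

    With ``root_terms``, keeps only sets inside the union of the roots'
    descendant closures (roots included). With ``end_level_only``, keeps
    only sets whose term has no children in the pruned graph. All
    criteria compose conjunctively.
    """
    if min_genes < 1:
        raise UsageError("min_genes must be >= 1")
    if max_genes < min_genes:
        raise UsageError("max_genes must be >= min_genes")
    if (root_terms or end_level_only) and graph is None:
        raise UsageError("hierarchy filters require an ontology graph")
    keep = [i for i, gs in collection.sets.items() if min_genes <= len(gs) <= max_genes]
    if root_terms is not None:
        if not graph.indexed:
            graph = prune_and_index(graph)
        allowed: set[str] = set()
        for root in root_terms:
            if root not in graph:
                raise DataError(f"unknown root term {root!r}")
            allowed.add(root)
            allowed |= graph.descendants(root)
        keep = [i for i in keep if i in allowed]
    if end_level_only:
        if not graph.indexed:
            graph = prune_and_index(graph)
        keep = [i for i in keep if i in graph and graph.is_leaf(i)]
    if not keep:
        warnings.warn("filter_collection produced an empty collection", stacklevel=2)
    return collection.subset(keep)


def resolve_names(
    ids: list[str], source: OntologyGraph | GeneSetCollection
) -> tuple[list[str], int]:
    """Map term ids to display names; unknown ids echo back.

    Returns (names, number of unknown ids). Total: never raises.
    """
    names: list[str] = []
    unknown = 0
    for i in ids:
        if isinstance(source, OntologyGraph) and i in source:
            names.append(source.name_of(i))
        elif isinstance(source, GeneSetCollection) and i in source:
            names.append(source[i].name)
        else:
            names.append(i)
            unknown += 1
    if unknown:
        logger.warning("resolve_names: %d unknown ids echoed back", unknown)
    return names, unknown
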