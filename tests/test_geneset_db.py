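"""Gene-set collection parsing, ontology pruning and hierarchy filtering."""
import numpy as np
import pytest

from pathcell import (DataError, ParseError, UsageError, filter_collection,
                      prune_and_index, read_edge_list, read_gaf_minimal,
                      read_gmt, read_obo_minimal, resolve_names,
                      simulate_ontology)
from conftest import write_gmt


def brute_force_descendants(graph, term):
    """Independent DFS oracle over the raw parent->child edge structure."""
    out, stack = set(), [term]
    while stack:
        node = stack.pop()
        for child in graph.children(node):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


# ------------------------------------------------------------------- GMT

def test_gmt_parses_sets_and_dedups(tmp_path):
    p = write_gmt(tmp_path / "a.gmt", [
        ["A", "set A", "g1", "g2", "g3"],
        ["B", "", "g1", "g1", "g2", "g4", "g5", "g6"],
    ])
    coll = read_gmt(p)
    assert len(coll) == 2
    assert coll["A"].name == "set A"
    assert coll["B"].name == "B"  # empty description falls back to id
    assert coll["B"].genes == ["g1", "g2", "g4", "g5", "g6"]


def test_gmt_rejects_short_lines_and_duplicate_ids(tmp_path):
    p = write_gmt(tmp_path / "short.gmt", [["A", "only-two-fields"]])
    with pytest.raises(ParseError, match=":1"):
        read_gmt(p)
    p = write_gmt(tmp_path / "dup.gmt", [
        ["GO:1", "x", "g1", "g2", "g3"],
        ["GO:1", "y", "g4", "g5", "g6"],
    ])
    with pytest.raises(ParseError, match="duplicate"):
        read_gmt(p)


# ------------------------------------------------------------------- GAF

def _gaf_row(symbol, term, aspect="P", qualifier=""):
    row = [""] * 15
    row[1], row[2], row[3], row[4], row[8] = "ID", symbol, qualifier, term, aspect
    return "\t".join(row)


def test_gaf_aggregates_and_filters(tmp_path):
    p = tmp_path / "a.gaf"
    p.write_text("\n".join([
        "!gaf-version: 2.2",
        _gaf_row("g1", "GO:1"), _gaf_row("g2", "GO:1"),
        _gaf_row("g3", "GO:2"), _gaf_row("g4", "GO:2", aspect="F"),
    ]) + "\n")
    coll = read_gaf_minimal(p)
    assert len(coll) == 2 and set(coll["GO:2"].genes) == {"g3", "g4"}
    only_p = read_gaf_minimal(p, aspect="P")
    assert only_p["GO:2"].genes == ["g3"]


def test_gaf_not_rows_dropped_and_empty_errors(tmp_path):
    p = tmp_path / "not.gaf"
    p.write_text(_gaf_row("g1", "GO:1", qualifier="NOT|involved_in") + "\n")
    with pytest.raises(DataError, match="no associations"):
        read_gaf_minimal(p)


# ------------------------------------------------------------------- OBO

OBO_CHAIN = """\
format-version: 1.2

[Term]
id: GO:0001
name: root process

[Term]
id: GO:0002
name: mid process
is_a: GO:0001

[Term]
id: GO:0003
name: leaf process
is_a: GO:0002
"""


def test_obo_chain_edges_and_roots(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(OBO_CHAIN)
    g = read_obo_minimal(p)
    assert g.roots == ["GO:0001"]
    assert g.children("GO:0001") == {"GO:0002"}
    assert g.children("GO:0002") == {"GO:0003"}


def test_obo_obsolete_flag_kept_until_pruning(tmp_path):
    p = tmp_path / "obs.obo"
    p.write_text(OBO_CHAIN.replace(
        "name: mid process", "name: mid process\nis_obsolete: true"))
    g = read_obo_minimal(p)
    assert g.is_obsolete("GO:0002")
    assert g.children("GO:0001") == {"GO:0002"}  # edges retained pre-pruning


def test_obo_self_reference_is_cycle_error(tmp_path):
    p = tmp_path / "self.obo"
    p.write_text("[Term]\nid: GO:1\nname: a\nis_a: GO:1\n")
    with pytest.raises(DataError, match="cycle"):
        read_obo_minimal(p)


def test_obo_dangling_reference_lists_offender(tmp_path):
    p = tmp_path / "dangle.obo"
    p.write_text("[Term]\nid: GO:1\nname: a\nis_a: GO:999\n")
    with pytest.raises(DataError, match="GO:999"):
        read_obo_minimal(p)


def test_edge_list_loader_equivalent(tmp_path):
    p = tmp_path / "edges.tsv"
    p.write_text(
        "child_id\tparent_id\tname\tobsolete\n"
        "T:1\t-\troot\t0\nT:2\tT:1\tmid\t1\nT:3\tT:2\tleaf\t0\n"
    )
    g = read_edge_list(p)
    assert g.roots == ["T:1"] and g.is_obsolete("T:2")


# ----------------------------------------------------------------- prune

def test_pruning_drops_obsolete_without_reattachment(tmp_path):
    p = tmp_path / "obs.obo"
    p.write_text(OBO_CHAIN.replace(
        "name: mid process", "name: mid process\nis_obsolete: true"))
    pruned = prune_and_index(read_obo_minimal(p))
    assert set(pruned.terms) == {"GO:0001", "GO:0003"}
    assert sorted(pruned.roots) == ["GO:0001", "GO:0003"]  # leaf becomes a root
    assert pruned.descendants("GO:0001") == set()


def test_pruning_all_obsolete_errors(tmp_path):
    p = tmp_path / "all.obo"
    p.write_text("[Term]\nid: GO:1\nname: a\nis_obsolete: true\n")
    with pytest.raises(DataError, match="every term"):
        prune_and_index(read_obo_minimal(p))


def test_no_obsolete_edges_after_pruning_on_random_fixtures():
    for seed in range(3):
        g, _ = simulate_ontology(3, 4, seed=seed, obsolete_fraction=0.3)
        pruned = prune_and_index(g)
        for term in pruned.terms:
            assert not pruned.is_obsolete(term)


@pytest.mark.parametrize("n_branches,depth", [(2, 3), (3, 4), (2, 5)])
def test_closures_match_brute_force_dfs(n_branches, depth):
    g, _ = simulate_ontology(n_branches, depth, seed=7)
    pruned = prune_and_index(g)
    assert len(pruned.terms) <= 200
    for term in pruned.terms:
        assert pruned.descendants(term) == brute_force_descendants(pruned, term)


def test_branch_descendant_count_closed_form(toy_ontology):
    g, _ = toy_ontology
    pruned = prune_and_index(g)
    for root in pruned.roots:
        assert len(pruned.descendants(root)) == 2 ** 3 - 2  # 2^depth - 1 minus self


# ---------------------------------------------------------------- filter

def test_size_filter(tmp_path):
    rows = [
        ["S5", "x"] + [f"a{i}" for i in range(5)],
        ["S50", "x"] + [f"b{i}" for i in range(50)],
        ["S800", "x"] + [f"c{i}" for i in range(800)],
    ]
    coll = read_gmt(write_gmt(tmp_path / "s.gmt", rows))
    out = filter_collection(coll, min_genes=10, max_genes=500)
    assert out.ids() == ["S50"]


def test_subtree_filter_matches_planted_branch(toy_ontology):
    g, coll = toy_ontology
    pruned = prune_and_index(g)
    branch = pruned.roots[0]
    expected = {t for t in pruned.descendants(branch) if t in coll}
    out = filter_collection(coll, pruned, root_terms=[branch])
    assert set(out.ids()) == expected and len(out) == 4  # 4 leaves per branch


def test_end_level_filter_on_chain(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(OBO_CHAIN)
    g = prune_and_index(read_obo_minimal(p))
    coll = read_gmt(write_gmt(tmp_path / "c.gmt", [
        ["GO:0001", "r", "g1", "g2"], ["GO:0002", "m", "g3", "g4"],
        ["GO:0003", "l", "g5", "g6"],
    ]))
    out = filter_collection(coll, g, end_level_only=True)
    assert out.ids() == ["GO:0003"]


def test_unknown_root_errors_and_empty_result_warns(toy_ontology, tmp_path):
    g, coll = toy_ontology
    pruned = prune_and_index(g)
    with pytest.raises(DataError, match="unknown root"):
        filter_collection(coll, pruned, root_terms=["NOPE:1"])
    with pytest.warns(UserWarning, match="empty"):
        out = filter_collection(coll, min_genes=1000)
    assert len(out) == 0


def test_filter_is_idempotent_and_commutes(toy_ontology):
    g, coll = toy_ontology
    pruned = prune_and_index(g)
    branch = pruned.roots[1]
    once = filter_collection(coll, pruned, min_genes=12, root_terms=[branch])
    twice = filter_collection(once, pruned, min_genes=12, root_terms=[branch])
    assert once.ids() == twice.ids()
    size_then_tree = filter_collection(
        filter_collection(coll, min_genes=12), pruned, root_terms=[branch])
    tree_then_size = filter_collection(
        filter_collection(coll, pruned, root_terms=[branch]), min_genes=12)
    assert set(size_then_tree.ids()) == set(tree_then_size.ids())


# --------------------------------------------------------------- resolve

def test_resolve_names_total_function(tmp_path):
    p = tmp_path / "n.obo"
    p.write_text("[Term]\nid: GO:0001\nname: T cell activation\n")
    g = read_obo_minimal(p)
    names, warn = resolve_names(["GO:0001"], g)
    assert names == ["T cell activation"] and warn == 0
    names, warn = resolve_names(["GO:0001", "GO:404"], g)
    assert names == ["T cell activation", "GO:404"] and warn == 1
    assert resolve_names([], g) == ([], 0)
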