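import random

import networkx as nx
import pytest

from conftest import make_registry
from synorth.errors import DataError
from synorth.formats_io import TandemFile
from synorth.network import (
    OrthoGroup,
    build_graph,
    compare_group_sets,
    connected_components,
    normalize_groups,
    summarize_groups,
)
from synorth.scoring import PairScore, ScoredBlock, ScoredPair
from synorth.tethers import build_tandem_arrays

REG = make_registry(
    [("spA", "c1", i, f"0_{i}") for i in range(8)]
    + [("spB", "c1", i, f"1_{i}") for i in range(8)]
)


def _block(pairs, block_id="b0"):
    scored = [ScoredPair(a, b, PairScore.PASS) for a, b in pairs]
    return ScoredBlock(block_id, "spA", "spB", "c1", "c1", "plus", scored)


def _arrays(pairs=()):
    return build_tandem_arrays(TandemFile(pairs=list(pairs)), REG)


def test_block_pairs_become_edges():
    arrays, _ = _arrays()
    block = _block([(f"0_{i}", f"1_{i}") for i in range(5)])
    g = build_graph([block], arrays, REG)
    assert g.number_of_edges() == 5
    assert sum(1 for n in g if g.degree(n) > 0) == 10


def test_duplicate_pairs_collapse_and_unknown_gene_fatal():
    arrays, _ = _arrays()
    b1 = _block([("0_0", "1_0")], "b1")
    b2 = _block([("0_0", "1_0")], "b2")
    g = build_graph([b1, b2], arrays, REG)
    assert g.number_of_edges() == 1
    with pytest.raises(DataError, match="unknown gene"):
        build_graph([_block([("0_0", "9_9")])], arrays, REG)


def test_tandem_array_chains_into_block_component():
    arrays, _ = _arrays([("0_0", "0_1"), ("0_1", "0_2")])
    block = _block([("0_1", "1_1")])
    g = build_graph([block], arrays, REG)
    comp = nx.node_connected_component(g, "1_1")
    assert {"0_0", "0_1", "0_2", "1_1"} <= comp


def test_components_partition_and_skip_isolated_vertices():
    arrays, _ = _arrays()
    blocks = [_block([("0_0", "1_0"), ("0_1", "1_0")], "b1"), _block([("0_2", "1_2")], "b2")]
    groups = connected_components(build_graph(blocks, arrays, REG), REG)
    memberships = [sorted(g.genes()) for g in groups]
    assert memberships == [["0_0", "0_1", "1_0"], ["0_2", "1_2"]]
    seen = [g for grp in groups for g in grp.genes()]
    assert len(seen) == len(set(seen))  # no gene in two groups


def test_empty_edge_set_yields_no_groups():
    arrays, _ = _arrays()
    assert connected_components(build_graph([], arrays, REG), REG) == []


def _bfs_oracle(edges, nodes):
    """Independent flood-fill: components via explicit BFS."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for n in sorted(nodes):
        if n in seen:
            continue
        comp, frontier = {n}, [n]
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    frontier.append(nxt)
        seen |= comp
        comps.append(frozenset(comp))
    return {c for c in comps if len(c) >= 2}


def test_components_match_flood_fill_oracle_on_random_graphs():
    rng = random.Random(42)
    for _ in range(30):
        n = rng.randint(2, 50)
        rows = [("spA", "c1", i, f"0_{i}") for i in range(n)]
        reg = make_registry(rows)
        nodes = [f"0_{i}" for i in range(n)]
        edges = [
            tuple(rng.sample(nodes, 2)) for _ in range(rng.randint(0, 2 * n))
        ]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        got = {frozenset(grp.genes()) for grp in connected_components(g, reg)}
        assert got == _bfs_oracle(edges, nodes)


# --- summaries ----------------------------------------------------------------


def _group(gid, **genes):
    return OrthoGroup(group_id=gid, genes_by_species={k: sorted(v) for k, v in genes.items()})


def test_summary_categories():
    arrays, array_of = _arrays([("0_3", "0_4")])
    ploidy = {"spA": 1, "spB": 1}
    groups = [
        _group("g0", spA=["0_0"], spB=["1_0"]),  # singleton + tether
        _group("g1", spA=["0_3", "0_4"]),  # species-specific, one tandem set
        _group("g2", spA=["0_5", "0_7"], spB=["1_5"]),  # 2 non-tandem sets: not tether
    ]
    summary = summarize_groups(groups, array_of, ploidy, ["spA", "spB"])
    assert summary.totals == {
        "total_groups": 3,
        "singleton_groups": 1,
        "tether_groups": 2,  # g0 and the tandem-only g1 (spB zero allowed)
        "species_specific_groups": 1,
        "genes_in_groups": 7,
    }
    sets_row = summary.per_group_genesets.set_index("group_id")
    assert sets_row.loc["g1", "spA"] == 1
    assert sets_row.loc["g2", "spA"] == 2


def test_polyploid_singleton_counts_ploidy_many_genes():
    arrays, array_of = _arrays()
    groups = [_group("g0", spA=["0_0", "0_2"], spB=["1_0"])]
    summary = summarize_groups(groups, array_of, {"spA": 2, "spB": 1}, ["spA", "spB"])
    assert summary.totals["singleton_groups"] == 1
    assert summary.totals["tether_groups"] == 1


# --- run comparison -------------------------------------------------------------


def _norm(groups):
    return [{sp: frozenset(genes) for sp, genes in g.items()} for g in groups]


def test_identical_runs_fully_agree():
    runs = _norm([{"A": ["a1"], "B": ["b1"]}, {"A": ["a2"], "B": ["b2"]}])
    report = compare_group_sets(runs, list(runs))
    assert report.n_identical == 2
    assert report.identical_fraction == 1.0
    assert report.clusters == []


def test_missing_group_is_unique_to_one_run():
    run1 = _norm([{"A": ["a1"], "B": ["b1"]}, {"A": ["a2"], "B": ["b2"]}])
    report = compare_group_sets(run1, run1[:1])
    assert report.n_identical == 1
    assert report.n_unique_run1 == 1
    assert report.n_unique_run2 == 0


def test_split_group_forms_complementary_cluster():
    run1 = _norm([{"A": ["a1", "a2"], "B": ["b1"]}])
    run2 = _norm([{"A": ["a1", "a2"]}, {"B": ["b1"]}])
    report = compare_group_sets(run1, run2)
    assert report.n_identical == 0
    assert len(report.clusters) == 1
    assert report.clusters[0].kind == "complementary"


def test_conflicting_membership_cluster():
    run1 = _norm([{"A": ["a1"], "B": ["b1"]}])
    run2 = _norm([{"A": ["a1"], "B": ["b2"]}])
    # overlap via a1; the two runs disagree about which B gene belongs
    report = compare_group_sets(run1, run2)
    assert len(report.clusters) == 1
    assert report.clusters[0].kind == "conflicting"


def test_gene_universe_mismatch_is_fatal():
    with pytest.raises(DataError, match="universes differ"):
        compare_group_sets([], [], {"a1"}, {"a1", "a2"})


def test_normalize_groups_requires_full_species_map():
    grp = OrthoGroup("g0", {"tetX": ["1_0"]})
    with pytest.raises(DataError, match="tetX"):
        normalize_groups([grp], {"dip": "dip"}, lambda g: g)
    out = normalize_groups([grp], {"tetX": "tet"}, lambda g: g.upper())
    assert out == [{"tet": frozenset({"1_0".upper()})}]
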