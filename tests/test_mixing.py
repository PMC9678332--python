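"""Mixing matrices, assortativity (vs brute-force and networkx), topology."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echochamber import (
    assortativity,
    attribute_assortativity,
    mixing_matrix,
    node_degrees,
    topology_summary,
)

from oracles import bf_assortativity, random_attr_graph


def _graph_from_chain(labels):
    """Undirected path with one node per label, unit weights."""
    g = nx.Graph()
    for i, lab in enumerate(labels):
        g.add_node(i, cat=lab)
    for i in range(len(labels) - 1):
        g.add_edge(i, i + 1, weight=1)
    return g


def test_single_directed_edge_concentrates_mass():
    g = nx.DiGraph()
    g.add_node(0, cat="A")
    g.add_node(1, cat="B")
    g.add_edge(0, 1, weight=3)
    m = mixing_matrix(g, "cat")
    iA, iB = m.categories.index("A"), m.categories.index("B")
    assert m.e[iA, iB] == 1.0 and m.e.sum() == pytest.approx(1.0)


def test_undirected_edge_splits_symmetrically():
    g = _graph_from_chain(["A", "B"])
    m = mixing_matrix(g, "cat")
    assert np.allclose(m.e, [[0, 0.5], [0.5, 0]])


def test_path_AABB_mixing_and_assortativity():
    # edges A-A, A-B, B-B: e_AA = e_BB = 1/3, e_AB = e_BA = 1/6; r = 1/3
    g = _graph_from_chain(["A", "A", "B", "B"])
    m = mixing_matrix(g, "cat")
    assert np.allclose(m.e, [[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
    assert assortativity(m).r == pytest.approx(1 / 3)


def test_two_same_attribute_cliques_are_perfectly_assortative():
    g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    nx.set_node_attributes(g, {n: ("A" if n < 3 else "B") for n in g.nodes}, "cat")
    assert attribute_assortativity(g, "cat").r == pytest.approx(1.0)


def test_complete_bipartite_graph_is_perfectly_disassortative():
    g = nx.complete_bipartite_graph(3, 3)
    nx.set_node_attributes(g, {n: ("A" if n < 3 else "B") for n in g.nodes}, "cat")
    assert attribute_assortativity(g, "cat").r == pytest.approx(-1.0)


def test_single_category_graph_flagged_degenerate():
    g = _graph_from_chain(["A", "A", "A"])
    res = assortativity(mixing_matrix(g, "cat"))
    assert res.degenerate and res.r == 0.0


def test_missing_attribute_raises_with_node_ids():
    g = nx.Graph()
    g.add_node("x", cat="A")
    g.add_node("y")
    g.add_edge("x", "y")
    with pytest.raises(KeyError, match="y"):
        mixing_matrix(g, "cat")


@settings(max_examples=120, derandomize=True, deadline=None)
@given(seed=st.integers(0, 100_000), directed=st.booleans(), weighted=st.booleans())
def test_assortativity_matches_brute_force_on_small_graphs(seed, directed, weighted):
    g = random_attr_graph(seed, max_nodes=6, directed=directed)
    if g.number_of_edges() == 0:
        return
    r = attribute_assortativity(g, "cat", weighted=weighted).r
    assert r == pytest.approx(bf_assortativity(g, "cat", weighted=weighted), abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 100_000))
def test_unweighted_assortativity_matches_networkx(seed):
    g = random_attr_graph(seed, max_nodes=6, directed=False)
    if g.number_of_edges() == 0:
        return
    ours = attribute_assortativity(g, "cat", weighted=False).r
    cats = {d["cat"] for _, d in g.nodes(data=True)}
    if len(cats) == 1:
        return
    ref = nx.attribute_assortativity_coefficient(g, "cat")
    if np.isnan(ref):
        return
    assert ours == pytest.approx(ref, abs=1e-9)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 100_000), scale=st.integers(2, 7))
def test_r_invariant_under_relabeling_and_weight_scaling(seed, scale):
    g = random_attr_graph(seed, max_nodes=6, directed=True)
    if g.number_of_edges() == 0:
        return
    r0 = attribute_assortativity(g, "cat").r
    swapped = g.copy()
    mapping = {"A": "B", "B": "C", "C": "A"}
    for _, d in swapped.nodes(data=True):
        d["cat"] = mapping[d["cat"]]
    for _, _, d in swapped.edges(data=True):
        d["weight"] *= scale
    assert attribute_assortativity(swapped, "cat").r == pytest.approx(r0, abs=1e-9)


def test_triangle_topology():
    g = nx.complete_graph(3)
    t = topology_summary(g)
    assert t.density == 1.0
    assert t.average_clustering == 1.0
    assert t.transitivity == 1.0
    assert t.reciprocity is None  # undirected: not applicable


def test_reciprocity_of_two_cycle_and_chain():
    g = nx.DiGraph([("u", "v"), ("v", "u")])
    assert topology_summary(g).reciprocity == pytest.approx(1.0)
    g = nx.DiGraph([("u", "v"), ("v", "w")])
    assert topology_summary(g).reciprocity == 0.0


def test_weighted_degrees_and_clustering():
    g = nx.DiGraph()
    for leaf in "abcd":
        g.add_edge(leaf, "center", weight=2)
    deg = node_degrees(g)
    assert deg.loc["center", "weighted_in_degree"] == 8
    assert deg.loc["a", "weighted_out_degree"] == 2
    # connect two of center's neighbors: their mutual triangle closes
    g.add_edge("a", "b", weight=1)
    deg = node_degrees(g)
    assert deg.loc["a", "clustering"] == 1.0
    g.add_node("loner")
    deg = node_degrees(g)
    assert deg.loc["loner", "weighted_in_degree"] == 0
    assert deg.loc["loner", "clustering"] == 0.0
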