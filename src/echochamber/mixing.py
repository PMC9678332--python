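"""Echo-chamber quantification: mixing matrices, assortativity, topology.

The echo chamber effect is measured by Newman's categorical assortativity

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i),

where ``e_ij`` is the fraction of edge weight running from category i to
category j, and ``a``/``b`` are its source/target marginals.  r = 1 means
edges only join same-category nodes (perfect homophily); r <= 0 means no
assortment.  Edge weights count as interaction multiplicities by default;
undirected edges contribute half their weight to each orientation so that
``e`` is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyCorpusError


@dataclass
class MixingMatrix:
    """Edge-weight fractions between attribute categories, with marginals."""

    categories: list[str]
    e: np.ndarray
    attribute: str = "attribute"

    @property
    def a(self) -> np.ndarray:  # source marginals
        return self.e.sum(axis=1)

    @property
    def b(self) -> np.ndarray:  # target marginals
        return self.e.sum(axis=0)


@dataclass
class AssortativityResult:
    r: float
    degenerate: bool = False
    attribute: str = "attribute"
    layer: str = ""
    mode: str = ""


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    average_clustering: float
    transitivity: float
    reciprocity: float | None  # None marks not-applicable (undirected graph)


def mixing_matrix(
    graph: nx.Graph, attribute: str, weighted: bool = True
) -> MixingMatrix:
    """Category-by-category edge-weight fractions for a node attribute.

    Raises ``KeyError`` naming the offending nodes if any lacks the attribute.
    """
    missing = [n for n, d in graph.nodes(data=True) if attribute not in d]
    if missing:
        raise KeyError(
            f"{len(missing)} node(s) missing attribute {attribute!r}: {missing[:5]}"
        )
    if graph.number_of_edges() == 0:
        raise EmptyCorpusError("graph has no edges; mixing matrix undefined")

    cats = sorted({d[attribute] for _, d in graph.nodes(data=True)})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    directed = graph.is_directed()
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1)) if weighted else 1.0
        i, j = idx[graph.nodes[u][attribute]], idx[graph.nodes[v][attribute]]
        if directed:
            e[i, j] += w
        else:
            e[i, j] += w / 2.0
            e[j, i] += w / 2.0
    e /= e.sum()
    return MixingMatrix(categories=cats, e=e, attribute=attribute)


def assortativity(m: MixingMatrix) -> AssortativityResult:
    """Newman's categorical assortativity coefficient from a mixing matrix.

    A single-category graph makes the denominator vanish; the result is then
    flagged degenerate with r = 0 rather than raising.
    """
    trace = float(np.trace(m.e))
    ab = float(m.a @ m.b)
    if abs(1.0 - ab) < 1e-12:
        return AssortativityResult(r=0.0, degenerate=True, attribute=m.attribute)
    return AssortativityResult(r=(trace - ab) / (1.0 - ab), attribute=m.attribute)


def attribute_assortativity(
    graph: nx.Graph, attribute: str, weighted: bool = True
) -> AssortativityResult:
    """Convenience: mixing matrix + assortativity in one call."""
    res = assortativity(mixing_matrix(graph, attribute, weighted=weighted))
    res.layer = graph.graph.get("layer", "")
    res.mode = graph.graph.get("mode", "")
    return res


def _undirected_projection(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((u, v) for u, v in graph.edges() if u != v)
    return g


def topology_summary(graph: nx.Graph) -> TopologySummary:
    """Density, clustering, transitivity and (directed only) reciprocity.

    Edge counts are unweighted.  Local clustering and transitivity are taken
    on the undirected unweighted projection; nodes of degree < 2 contribute 0
    to the average.  Reciprocity is the fraction of directed edges whose
    reverse also exists; ``None`` for undirected graphs.
    """
    if graph.number_of_nodes() == 0:
        raise EmptyCorpusError("graph has no nodes")
    proj = _undirected_projection(graph)
    n = graph.number_of_nodes()
    clustering = sum(nx.clustering(proj).values()) / n
    reciprocity = None
    if graph.is_directed():
        reciprocity = float(nx.reciprocity(graph)) if graph.number_of_edges() else 0.0
    return TopologySummary(
        n_nodes=n,
        n_edges=graph.number_of_edges(),
        density=float(nx.density(graph)),
        average_clustering=float(clustering),
        transitivity=float(nx.transitivity(proj)),
        reciprocity=reciprocity,
    )


def node_degrees(graph: nx.Graph) -> pd.DataFrame:
    """Per-node weighted in/out degree and local clustering coefficient.

    For undirected graphs the in- and out-degree columns coincide.  The
    clustering coefficient is computed on the undirected unweighted
    projection (0 for nodes of degree < 2).
    """
    if graph.number_of_nodes() == 0:
        raise EmptyCorpusError("graph has no nodes")
    proj = _undirected_projection(graph)
    clust = nx.clustering(proj)
    if graph.is_directed():
        win = dict(graph.in_degree(weight="weight"))
        wout = dict(graph.out_degree(weight="weight"))
    else:
        win = wout = dict(graph.degree(weight="weight"))
    nodes = list(graph.nodes)
    return pd.DataFrame(
        {
            "weighted_in_degree": [float(win[n]) for n in nodes],
            "weighted_out_degree": [float(wout[n]) for n in nodes],
            "clustering": [float(clust[n]) for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
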