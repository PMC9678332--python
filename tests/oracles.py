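"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by direct enumeration of the defining
formula, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def bf_assortativity(graph: nx.Graph, attribute: str, weighted: bool = True) -> float:
    """Categorical assortativity by direct edge enumeration.

    Builds the mixing fractions with plain dicts and applies
    r = (sum e_ii - sum a_i b_i) / (1 - sum a_i b_i).
    """
    e: dict[tuple, float] = {}
    total = 0.0
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1)) if weighted else 1.0
        cu, cv = graph.nodes[u][attribute], graph.nodes[v][attribute]
        if graph.is_directed():
            e[(cu, cv)] = e.get((cu, cv), 0.0) + w
        else:
            e[(cu, cv)] = e.get((cu, cv), 0.0) + w / 2
            e[(cv, cu)] = e.get((cv, cu), 0.0) + w / 2
        total += w
    cats = sorted({d[attribute] for _, d in graph.nodes(data=True)})
    a = {c: sum(e.get((c, d), 0.0) for d in cats) / total for c in cats}
    b = {c: sum(e.get((d, c), 0.0) for d in cats) / total for c in cats}
    diag = sum(e.get((c, c), 0.0) for c in cats) / total
    ab = sum(a[c] * b[c] for c in cats)
    if abs(1 - ab) < 1e-12:
        return 0.0
    return (diag - ab) / (1 - ab)


def _sym(graph: nx.Graph) -> dict:
    z: dict = {n: {} for n in graph.nodes}
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = float(d.get("weight", 1))
        z[u][v] = z[u].get(v, 0.0) + w
        z[v][u] = z[v].get(u, 0.0) + w
    return z


def bf_structural_holes(graph: nx.Graph, ego) -> dict:
    """Burt's four indices by literal triple loops over the formulas."""
    z = _sym(graph)
    contacts = [q for q in graph.nodes if z[ego].get(q, 0.0) > 0]
    assert contacts, "oracle called on isolated ego"
    n = len(contacts)

    def p(i, j):
        s = sum(z[i].values())
        return z[i].get(j, 0.0) / s

    constraint = 0.0
    c = {}
    for j in contacts:
        indirect = 0.0
        for q in contacts:
            if q != j:
                indirect += p(ego, q) * p(q, j)
        c[j] = (p(ego, j) + indirect) ** 2
        constraint += c[j]

    eff = 0.0
    for j in contacts:
        red = 0.0
        for q in contacts:
            if q == j:
                continue
            m = z[j].get(q, 0.0) / max(z[j].values())
            red += p(ego, q) * m
        eff += 1.0 - red

    if n == 1:
        hierarchy = 0.0
    else:
        mean_c = constraint / n
        hierarchy = sum(
            (c[j] / mean_c) * math.log(c[j] / mean_c) for j in contacts
        ) / (n * math.log(n))
    return {
        "n_contacts": n,
        "effective_size": eff,
        "efficiency": eff / n,
        "constraint": constraint,
        "hierarchy": hierarchy,
    }


def bf_chi_square(table) -> tuple[float, int]:
    """Pearson statistic by direct O/E summation."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def random_attr_graph(
    seed: int, max_nodes: int = 6, directed: bool = False, attribute: str = "cat"
) -> nx.Graph:
    """Random small weighted graph with a categorical node attribute."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    g = nx.DiGraph() if directed else nx.Graph()
    cats = ["A", "B", "C"]
    for i in range(n):
        g.add_node(i, **{attribute: cats[rng.integers(0, 3)]})
    for i in range(n):
        for j in range(n):
            if i == j or (not directed and i > j):
                continue
            if rng.random() < 0.6:
                g.add_edge(i, j, weight=int(rng.integers(1, 6)))
    return g
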