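"""Burt's ego-network structural-hole indices on the weighted user network.

All four indices work on symmetrized tie strengths z'(u, v) = z(u, v) +
z(v, u), where z is the directed interaction count.  For an ego i with
contact set N(i) (union of in- and out-neighbors, |N(i)| = N):

proportional tie strength
    p_ij = z'(i, j) / sum_k z'(i, k)

dyadic constraint
    c_ij = (p_ij + sum_q p_iq p_qj)^2 over q in N(i) \\ {i, j}; aggregate
    constraint C_i = sum_j c_ij.  C_i can exceed 1 for egos with few,
    interlocked contacts (e.g. 1.125 for a node of a triangle): "between 0
    and 1" is an informal description, not a clamp.

effective size
    S_i = N - sum_j sum_q p_iq m_jq with m_jq = z'(j, q) / max_k z'(j, k),
    the marginal strength of contact j's tie to q; q again over the ego's
    other contacts.  Efficiency E_i = S_i / N.

hierarchy (Coleman-Theil concentration of the c_ij)
    H_i = sum_j (c_ij / (C_i/N)) ln(c_ij / (C_i/N)) / (N ln N); 0 when all
    dyadic constraints are equal (or N = 1), 1 when concentrated in one tie.

Isolated egos have no contacts and all four indices undefined; batch
computation lists them separately instead of raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import EmptyCorpusError, UndefinedMetricsError


@dataclass
class TieProfile:
    ego: object
    contacts: list
    p: dict          # proportional tie strengths p_ij
    c: dict          # dyadic constraints c_ij

    @property
    def constraint(self) -> float:
        return sum(self.c.values())


@dataclass
class NodeSHMetrics:
    ego: object
    n_contacts: int
    effective_size: float
    efficiency: float
    constraint: float
    hierarchy: float


def _sym_weights(graph: nx.Graph) -> dict:
    """z'(u, v) = z(u, v) + z(v, u) as a dict of dicts over undirected pairs."""
    z: dict = {n: {} for n in graph.nodes}
    for u, v, d in graph.edges(data=True):
        if u == v:
            continue
        w = float(d.get("weight", 1))
        z[u][v] = z[u].get(v, 0.0) + w
        z[v][u] = z[v].get(u, 0.0) + w
    return z


def _p_row(z: dict, node) -> dict:
    total = sum(z[node].values())
    return {k: w / total for k, w in z[node].items()}


def tie_profile(graph: nx.Graph, ego) -> TieProfile:
    """Proportional tie strengths and dyadic constraints for one ego."""
    z = _sym_weights(graph)
    return _tie_profile_from(z, ego)


def _tie_profile_from(z: dict, ego, p_cache: dict | None = None) -> TieProfile:
    if ego not in z:
        raise KeyError(f"node {ego!r} not in graph")
    contacts = sorted(z[ego], key=str)
    if not contacts:
        raise UndefinedMetricsError(f"ego {ego!r} is isolated; metrics undefined")
    if p_cache is None:
        p_cache = {}
    if ego not in p_cache:
        p_cache[ego] = _p_row(z, ego)
    p_ego = p_cache[ego]
    for q in contacts:
        if q not in p_cache:
            p_cache[q] = _p_row(z, q)
    p_rows = p_cache
    c = {}
    for j in contacts:
        indirect = sum(
            p_ego[q] * p_rows[q].get(j, 0.0) for q in contacts if q != j
        )
        c[j] = (p_ego[j] + indirect) ** 2
    return TieProfile(ego=ego, contacts=contacts, p=p_ego, c=c)


def sh_metrics(graph: nx.Graph, ego) -> NodeSHMetrics:
    """Effective size, efficiency, constraint and hierarchy for one ego."""
    z = _sym_weights(graph)
    return _sh_metrics_from(z, ego)


def _sh_metrics_from(z: dict, ego, p_cache: dict | None = None) -> NodeSHMetrics:
    profile = _tie_profile_from(z, ego, p_cache)
    contacts = profile.contacts
    n = len(contacts)
    p_ego = profile.p

    redundancy = 0.0
    for j in contacts:
        maxw = max(z[j].values())  # j has at least the tie to ego
        redundancy += sum(
            p_ego[q] * (z[j].get(q, 0.0) / maxw) for q in contacts if q != j
        )
    s = n - redundancy
    constraint = profile.constraint

    if n == 1:
        hierarchy = 0.0
    else:
        mean_c = constraint / n
        hierarchy = sum(
            (cij / mean_c) * math.log(cij / mean_c) for cij in profile.c.values()
        ) / (n * math.log(n))
    return NodeSHMetrics(
        ego=ego,
        n_contacts=n,
        effective_size=s,
        efficiency=s / n,
        constraint=constraint,
        hierarchy=hierarchy,
    )


def sh_table(graph: nx.Graph) -> tuple[pd.DataFrame, list]:
    """Structural-hole indices for every non-isolated node.

    Returns ``(table, isolated)``: a frame indexed by node id with columns
    n_contacts / effective_size / efficiency / constraint / hierarchy, and
    the list of isolated nodes excluded from it.
    """
    if graph.number_of_nodes() == 0:
        raise EmptyCorpusError("graph has no nodes")
    z = _sym_weights(graph)
    p_cache: dict = {}
    rows, isolated = [], []
    for node in graph.nodes:
        if not z[node]:
            isolated.append(node)
            continue
        m = _sh_metrics_from(z, node, p_cache)
        rows.append(
            {
                "node": node,
                "n_contacts": m.n_contacts,
                "effective_size": m.effective_size,
                "efficiency": m.efficiency,
                "constraint": m.constraint,
                "hierarchy": m.hierarchy,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "node",
            "n_contacts",
            "effective_size",
            "efficiency",
            "constraint",
            "hierarchy",
        ],
    ).set_index("node")
    return table, isolated
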