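"""Burt's structural-hole indices on hand-sized graphs.

A star center touches contacts that ignore each other: maximal effective
size, minimal constraint — the profile of a broker.  A triangle node's
contacts are interlocked: redundancy pushes constraint above 1.  Hierarchy
is 0 whenever the dyadic constraints are evenly spread.
"""

import networkx as nx

from echochamber import sh_metrics, sh_table

star = nx.star_graph(4)
nx.set_edge_attributes(star, 1, "weight")
tri = nx.complete_graph(3)
nx.set_edge_attributes(tri, 1, "weight")

print("graph           S      E      C      H")
for name, g, ego in (("star center", star, 0), ("star leaf", star, 1),
                     ("triangle node", tri, 0)):
    m = sh_metrics(g, ego)
    print(f"{name:<14} {m.effective_size:>5.2f}  {m.efficiency:>5.2f}  "
          f"{m.constraint:>5.3f}  {m.hierarchy:>5.3f}")

# kite: node 'b' bridges a clique and a pendant -> lowest constraint
kite = nx.Graph()
for u, v in [("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")]:
    kite.add_edge(u, v, weight=1)
table, _ = sh_table(kite)
print("\nkite graph (d hangs off b):")
print(table.round(3))
print("lowest constraint:", table["constraint"].idxmin(),
      "- the broker between the clique and the pendant")
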