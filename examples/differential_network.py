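"""Differential co-expression network from a curated edge set plus data.

Within each group the Spearman correlation of every gene pair is computed
with an exact permutation p-value (n = 5 per arm here).  Edges are the
union of the illustrative curated set (55 edges) and novel pairs passing
|rho| >= 0.9 with significance in either group; each edge carries a Fisher
r-to-z test of the between-group correlation change.
"""

from dcoex import build_network, topology
from dcoex.fixtures import demo_network_inputs

expr, groups, curated = demo_network_inputs()
G = build_network(expr, groups, curated)

sources = [d["source"] for _, _, d in G.edges(data=True)]
print(f"nodes: {G.number_of_nodes()}, edges: {G.number_of_edges()} "
      f"({sources.count('curated')} curated + {sources.count('novel')} novel)")

report, nodes = topology(G)
print(f"density = {report.density:.3f}, avg neighbors = {report.avg_neighbors:.3f}")
print(f"clustering = {report.clustering_coefficient:.3f}, "
      f"path length = {report.char_path_length:.3f}, "
      f"diameter = {report.diameter:g}, radius = {report.radius:g}")
print(f"heterogeneity = {report.heterogeneity:.3f}, "
      f"centralization = {report.centralization:.3f}")

hub = nodes["degree"].idxmax()
print(f"\nhub: {hub} (degree {nodes.loc[hub, 'degree']}, "
      f"betweenness {nodes.loc[hub, 'betweenness']:.3f}, "
      f"closeness {nodes.loc[hub, 'closeness']:.3f})")

changed = sorted(
    ((abs(d["z_change"]), u, v) for u, v, d in G.edges(data=True)
     if d["z_change"] == d["z_change"]),
    reverse=True,
)[:3]
print("largest correlation changes (|z|):")
for z, u, v in changed:
    d = G.edges[u, v]
    print(f"  {u}-{v}: rho {d['rho_g1']:+.2f} -> {d['rho_g2']:+.2f} "
          f"({d['direction']}, z = {d['z_change']:+.2f})")
# High centralization with one dominant hub indicates a hub-driven
# architecture; strengthened edges are correlations larger in the case arm.
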