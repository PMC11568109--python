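"""Count 2-4-node graphlets on a toy network and build a graphlet adjacency.

The paw graph (a triangle a-b-c with a pendant d on a) makes the counts
easy to read: there is one triangle (G2), one paw (G6) and two induced
3-paths (G1: b-a-d and c-a-d).
"""

from gracoal import Network, count_graphlets, graphlet_adjacency, normalize_adjacency

net = Network([("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")])
counts = count_graphlets(net)

print("graphlet occurrence totals (G0..G8):", list(counts.graphlet_totals()))
print()
print("node  t_u(G0) t_u(G1) t_u(G2) t_u(G6)")
for i, u in enumerate(counts.nodes):
    t = counts.node_counts[i]
    print(f"{u:>4}  {t[0]:>7} {t[1]:>7} {t[2]:>7} {t[6]:>7}")
print()
print("c_ad(G1) =", counts.pair_count(1, "a", "d"), "(a and d co-occur on both induced 3-paths)")

adj = normalize_adjacency(graphlet_adjacency(counts, 2))
print()
print("normalized triangle adjacency (rows/cols in node order", adj.nodes, "):")
print(adj.matrix.round(3))
print("d has no triangles, so its row is zero and it would be dropped from a G2 embedding")
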