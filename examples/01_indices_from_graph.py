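"""Compute all twelve topological indices of one molecular graph.

Builds the hydrogen-suppressed skeleton of tranylcypromine (a phenyl
ring fused to a cyclopropane carrying an amine), extracts its degree-
and neighborhood-degree-based edge partitions and aggregates the twelve
edge-contribution formulas over each.
"""

from topoqspr import DEGREE, NEIGHBORHOOD, compute_all_indices, edge_partition, read_graph

EDGES = """
c1 c2
c2 c3
c3 c4
c4 c5
c5 c6
c6 c1
c1 c7
c7 c8
c8 c9
c9 c7
c8 n10
"""

graph = read_graph(EDGES)
print(f"graph: {graph.n_vertices} heavy atoms, {graph.n_edges} bonds")

for flavor in (DEGREE, NEIGHBORHOOD):
    part = edge_partition(graph, flavor)
    print(f"\n{flavor} partition: {dict(sorted(part.counts.items()))}")
    vec = compute_all_indices(part).round(2)
    print(vec.to_string())

# The Randic values 4.88 (degree) and 2.11 (neighborhood) are the
# worked reference values for this drug; ReZ1 over the degree partition
# equals the heavy atom count (10) exactly.
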