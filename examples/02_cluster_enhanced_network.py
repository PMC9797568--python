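"""Cluster an attribute-enhanced interaction network.

Generates a planted four-community interaction graph with
cluster-correlated fold changes, builds the enhanced graph (high-
confidence edges weighted by interaction confidence x fold-change
similarity), tunes the MCL inflation by modularity, and compares the
recovered partition with the planted one.
"""

from sklearn.metrics import adjusted_rand_score

from stressweave import clustering, enhance, synthetic

spec = synthetic.SyntheticSpec(seed=7)
edges, fold_changes, truth = synthetic.generate_network(spec)
graph = enhance.build_enhanced_graph(edges, fold_changes)
print(f"enhanced graph: {graph.number_of_nodes()} genes, {graph.number_of_edges()} edges")

inflation, solution = clustering.tune_inflation(graph, grid=(1.4, 2.0, 3.0, 4.0))
nodes = sorted(graph.nodes)
ari = adjusted_rand_score(
    [truth.gene_cluster[n] for n in nodes], [solution.partition[n] for n in nodes]
)
print(f"tuned inflation r = {inflation}, modularity Q = {solution.modularity:.3f}")
print(f"clusters found = {solution.n_clusters}, adjusted Rand index vs planted = {ari:.2f}")
print(
    "\nAn ARI of 1.0 means the Markov clustering recovered exactly the four "
    "planted co-expression communities from the weighted topology."
)

clustering.annotate_solution(solution, {n: graph.nodes[n]["log2fc"] for n in nodes})
for cid, st in sorted(solution.stats.items()):
    print(f"cluster {cid}: {st.size} genes, median log2FC {st.median:+.2f} ({st.direction})")
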