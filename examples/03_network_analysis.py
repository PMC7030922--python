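"""Interaction-network statistics on a planted-module graph.

Generates a 4-module planted-partition graph with module-aligned annotation
terms, clusters it with deterministic edge-betweenness (Girvan-Newman)
clustering, and compares the co-annotation of edges against a
degree-preserving rewired null.
"""

import networkx as nx
import numpy as np

from xlmap.network import (
    coannotation_statistic,
    degree_powerlaw_fit,
    girvan_newman_cluster,
    rewire_null,
)
from xlmap.synthetic import make_planted_network

graph, truth, annotations = make_planted_network(
    k=4, size=25, p_in=0.3, p_out=0.01, seed=17
)
core = graph.subgraph(max(nx.connected_components(graph), key=len)).copy()

partition = girvan_newman_cluster(core)
print(f"core component:    {core.number_of_nodes()} nodes, {core.number_of_edges()} edges")
print(f"clusters found:    {partition.n_clusters} (planted: 4)")
print(f"modularity Q:      {partition.modularity:.3f}")

slope, intercept, r2 = degree_powerlaw_fit(graph)
print(f"degree log-log fit: slope {slope:.2f}, R^2 {r2:.2f} "
      "(planted-partition graphs are Poisson-like, not scale-free, so the fit is flat)")

null = rewire_null(core, n_iter=50, seed=17)
result = coannotation_statistic(core, annotations, null, min_proteins=0)
for term, obs in sorted(result.per_term_observed.items()):
    null_mean = result.per_term_null[term].mean()
    print(f"  {term}: observed co-annotation {obs:.3f} vs null mean {null_mean:.3f}")
print(f"KS test observed vs null: D={result.ks_statistic:.3f}, p={result.ks_pvalue:.2e}")

# Edges inside planted modules share their module's term far more often than
# in degree-matched rewired graphs - the signature of a modular network whose
# clusters carry coherent annotations.
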