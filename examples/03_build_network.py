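"""Build one condition's weighted coexpression network.

Runs the full network stage for the IFN-alpha arm: |cor|^8 adjacency ->
topological overlap -> average-linkage dendrogram -> dynamic tree cut ->
eigengene merging, then reports module sizes, the strongest intramodular hub,
and the top of the 50,000-edge export with betweenness centrality.
"""

from ascnet import (
    betweenness,
    build_network,
    filter_undetected,
    quantile_normalize,
    recovery_benchmark_config,
    simulate_timecourse,
    top_edges,
)

x, det, truth = simulate_timecourse(recovery_benchmark_config(seed=0))
xq = quantile_normalize(filter_undetected(x, det))
net = build_network(xq, "ifn_alpha", power=8, min_size=8, cut_height=0.995, merge_cut=0.2)

part = net.partition
print("module sizes (grey = unassigned):")
print(part.sizes().to_string())
print(f"grey fraction: {part.grey_fraction:.2f}")

hub = part.kwithin.idxmax()
print(
    f"\nstrongest hub: {hub} (kWithin = {part.kwithin.max():.1f}, "
    f"module {part.labels[hub]}, planted as {truth.labels[hub]})"
)

edges = top_edges(net.tom, budget=50_000)
print(f"\ntop of the edge list ({len(edges)} edges retained):")
print(edges.head(5).to_string(index=False))
bc = betweenness(edges.head(2000))
print(f"\nhighest betweenness in the strongest 2000 edges: {bc.idxmax()} ({bc.max():.0f})")
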