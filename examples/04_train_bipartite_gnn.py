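"""Bipartite link prediction: drug-pair nodes vs side-effect nodes.

Builds the graph from the planted fixture, splits edges 80/10/10 with the
30/70 supervision/message partition inside the training set, trains the
encoder-decoder GNN, and scores held-out edges against sampled non-edges.
"""

import polysides as ps

table, pair_features, se_features, _ = ps.standard_fixture(seed=7)
graph = ps.build_graph(table, pair_features, se_features)
print(f"graph: {graph.n_pairs} pair nodes, {graph.n_se} side-effect nodes, "
      f"{len(graph.edges)} edges")

split = ps.split_edges(graph, seed=7)
print(f"edges: {len(split.supervision)} supervision / {len(split.message)} message "
      f"/ {len(split.val)} val / {len(split.test)} test")

model, log = ps.train_gnn(graph, split, ps.toy_config(seed=7))
print(f"trained for {len(log)} epochs "
      f"(best val AUROC {max(e['val_auroc'] for e in log):.3f})")

result = ps.evaluate_split(model, graph, split, "test")
print(f"test AUROC {result['auroc']:.3f}, AUPRC {result['auprc']:.3f}, "
      f"AP@50 {result['ap50']:.3f}")

# Test edges are scored with messages passing over train+val edges (the
# transductive protocol): every node is known, only edges are held out.
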