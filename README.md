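# polysides

Polypharmacy — co-prescribing two or more drugs — causes adverse events
that neither drug produces alone. `polysides` predicts which side effects
a drug *pair* is associated with, using only the drugs' chemical
structures (SMILES strings) as input. It implements two classifiers over
a shared drug-pair representation:

1. **Multi-label MLP** — each drug's SMILES is embedded to a vector `e`;
   the pair representation is the sum `e_pair = e1 + e2`; a feed-forward
   network with sigmoid outputs predicts one probability per side effect.
2. **Bipartite graph link prediction** — a graph `G = (D, S, E, F)` with
   drug-pair nodes `D`, side-effect nodes `S`, association edges `E` and
   node features `F`. An encoder stack of graph convolutions

   ```
   h_i^(k) = W1^(k) h_i^(k-1) + W2^(k) Σ_{j∈N(i)} h_j^(k-1)
   ```

   updates node states; a dot-product decoder `s_ij = h_i · h_j` scores a
   candidate (pair, side-effect) edge, and `σ(s_ij)` is the association
   probability. Training is transductive: edges split 80/10/10, with 30%
   of training edges used for supervision and 70% reserved for message
   passing, plus one sampled non-edge per positive.

Evaluation is threshold-free: AUROC, AUPRC, and AP@50 (the mean of top-k
precision for k = 1..50 of the ranked predictions), reported globally
(micro and macro) and per side effect with best/worst tables.

The package reads association tables in the common drug-pair/side-effect
layout (columns `STITCH 1`, `STITCH 2`, `Polypharmacy Side Effect`,
`Side Effect Name`), resolves CIDs to SMILES from a local chemistry CSV,
and audits structural uniqueness via RDKit InChIKeys. A seeded synthetic
generator plants a low-rank pair↔side-effect structure so the entire
pipeline is testable offline.

It is intended for computational drug-safety researchers who want a
self-contained, dependency-light reference implementation of this
pipeline with verifiable numerics.

## Worked example

```python
import polysides as ps

table, pair_features, se_features, _ = ps.standard_fixture(seed=7)
graph = ps.build_graph(table, pair_features, se_features)
split = ps.split_edges(graph, seed=7)
model, log = ps.train_gnn(graph, split, ps.toy_config(seed=7))
print(ps.evaluate_split(model, graph, split, "test"))
```

prints (after ~300 training epochs, ~15 s on one CPU core):

```
{'auroc': 0.904, 'auprc': 0.909, 'ap50': 1.000}
```

The fixture plants a rank-8 structure over 80 drugs and 25 side effects:
side effect `s` fires for pair `(a, b)` with probability
`σ(⟨u_a + u_b, v_s⟩ + b_s)`. A test AUROC of 0.90 (against a
Bayes-optimal ceiling of ≈0.95 at this signal strength) means the GNN
recovered most of the planted structure from the observed edges and the
noisy features; on a randomly rewired control graph the same model scores
≈0.5, confirming the signal is real rather than an artifact of degrees or
training. The scripts in `examples/` walk through each stage the same
way (data preparation, embedding/fusion, both classifiers, metrics,
fusion comparison).

A thin CLI mirrors the library:

```bash
polysides simulate --seed 7 --out sim/
polysides prepare --associations sim/associations.csv \
    --chemistry sim/chemistry.csv --min-pairs 1 --out prep/
polysides run --seed 7 --out runs/demo
```

## Testing

```bash
python -m pytest -q tests/
```

The suite verifies the metrics against brute-force oracles, the graph
convolution against a per-node double loop, the focal loss against hand
evaluations, split/negative-sampling invariants, and end-to-end recovery
of planted structure by both classifiers (with shuffled and
zero-information negative controls).

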