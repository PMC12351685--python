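# Methods

## Problem and data model

The unit of prediction is an unordered drug pair. The raw input is a long
association table — one row per (drug A, drug B, side effect) assertion —
plus a chemistry table mapping drug ids to SMILES. Two reshapes produce
the classifier inputs:

* **Multi-label table**: pairs are canonicalized (lexicographic order on
  the id strings; the raw tables do not specify how swapped-order
  duplicates merge, so we fix a reproducible convention), and each pair's
  side effects are unioned into one row. Conservation holds by
  construction: the sum of row-set sizes equals the number of distinct
  (pair, side effect) assertions.
* **Bipartite graph**: one node per pair row, one per vocabulary entry,
  one edge per assertion.

The frequency filter keeps side effects present in at least `min_pairs`
*distinct canonical pairs* (not raw rows); 500 is the conventional
threshold on the full-scale data. The side-effect vocabulary is sorted by
id so multi-hot indices are stable across runs.

## Embeddings and fusion

Every encoder satisfies one contract: `encode_batch: [str] -> (n, dim)`
matrix, deterministic for fixed provider state, inputs truncated at
`max_len` = 64 characters (SMILES in the reference corpus average ~54
characters, so 64 preserves most strings). Pretrained chemical/text
language models are adapters behind this contract and are not exercised
offline; the working offline encoder is character n-gram feature hashing
(n = 1..3, seeded blake2 hash into `dim` buckets with a hashed sign, L2
normalization). It is not a learned representation — it is a
deterministic locality-sensitive fingerprint that makes the full pipeline
runnable and testable with no downloads.

Pair fusion defaults to summation, `e_pair = e1 + e2`: symmetric in the
two drugs and dimension-preserving. `mean`, `concat` and elementwise
`product` are selectable for the fusion comparison. Side-effect names are
lowercased before text encoding (casing carries no signal in these
vocabularies).

## Multi-label MLP

Architecture: input → per hidden layer [linear → batchnorm (first hidden
layer only) → leaky-ReLU (slope 0.1) → dropout 0.2] → linear → sigmoid.
Batchnorm is placed after the first hidden layer only; the first layer
sees raw fused embeddings whose scale varies across encoders, while
normalizing deeper layers disturbs the learned intermediate
distributions. Full-scale defaults: hidden sizes 512/1024/2048, output
one sigmoid per side effect.

Loss is binary focal cross-entropy, mean over all (pair, side effect)
cells: `-α_t (1 - p_t)^γ log p_t` with `p_t = p` for positive cells and
`1 - p` otherwise. γ = 2, α = 0.25 are the conventional focal defaults
(the loss's source leaves them free); γ = 0, α = 0.5 reduces exactly to
half the ordinary BCE, which the tests verify. Optimization is Adam with
base rate 0.005 decayed exponentially per epoch (×0.96), batch 512, up to
100 epochs, early stopping on validation loss with patience 10 and
best-checkpoint restore. Rows split 80/10/10; 10 cross-validation folds
tile the train+val indices only, so test rows never enter any fold.

Gradients are hand-derived (the focal gradient is computed with respect
to the logit for stability, with probabilities clipped at 1e-12), and
verified indirectly through the recovery experiments; the loss itself is
verified against closed-form values.

## Bipartite GNN

Initial node state = learned per-node ID embedding (width 64) + one-layer
linear projection of the node's feature (pair embedding or side-effect
name embedding) to the same width; the sum keeps the state width fixed
and lets either term be ablated. The encoder applies `conv_layers` = 2
graph convolutions, `h' = W1 h + W2 Σ_neighbors h`, with ReLU and dropout
between layers. Messages flow in both directions (reversed edges are
added for message passing only). The decoder is the dot product of final
states; BCE-with-logits on supervision positives plus an equal number of
freshly sampled non-edges per epoch. Validation/test negatives are drawn
once per split so metrics are comparable across epochs.

Two numerical choices matter on dense graphs and are our own additions
around the fixed layer equation:

* **Degree-aware initialization** — the neighbor weights `W2` are
  initialized a factor of mean-degree smaller than `W1`. Sum aggregation
  (no degree normalization, per the layer definition) otherwise produces
  initial states, and hence dot-product logits, that grow with node
  degree and saturate the loss before learning starts.
* **Final-state L2 normalization with a learned global scale** — the
  protocol evaluates with larger message graphs than it trains on (val:
  all train edges; test: train+val edges), so node-state magnitudes shift
  with degree between phases. Normalizing rows of the final state matrix
  makes the decoder compare directions, which transfers across message
  graphs; a single learned scalar scale restores confident logit
  magnitudes. Both are on by default and configurable.

Early stopping monitors validation AUROC (patience 5 at full-scale
defaults) with best-checkpoint restore. The backward pass through the
conv stack, projections, ID embeddings and normalization is hand-derived
and was verified against central-difference numerical gradients to ~1e-10
during development.

The zero-filled-features baseline (constant zero features of width 200,
ID embeddings active) is available as a config preset; disabling both
features and ID embeddings collapses all states to zero and yields
chance-level scores, which serves as the no-information control.

## Metrics

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative (ties ½); AUPRC sums precision over recall increments of
the ranked list; both are computed via scikit-learn and cross-checked in
the tests against independent brute-force implementations. AP@50 sorts
predictions by descending score (stable sort; ties keep input order) and
averages `AP(k) = TP@k / k` over k = 1..50 (k truncates to n on short
lists). The upper summation bound is read as 50 — the only reading
consistent with the metric's name.

Per-side-effect reports compute each group's metrics, macro (group mean)
and micro (pooled) summaries, and best/worst tables ordered by AUPRC;
single-class groups are excluded from macro averages and listed
explicitly. MLP evaluation is column-wise over test pairs; GNN evaluation
is per test edge against the fixed test negatives. Both micro and macro
are always reported because the two diverge strongly under class
imbalance.

## Synthetic generator

The generator is the package's testbed and defines its reference
conditions. Each drug carries a latent `u ~ N(0, I_k)`; each side effect
a latent `v ~ N(0, (signal²/k) I_k)` and a base-rate offset
`b_s = bias − skew · log(rank_s)`. Edge probability for pair (a, b) and
side effect s is `σ(⟨u_a + u_b, v_s⟩ + b_s)` — additive in the drugs, so
sum-fusion is correctly specified by construction, and low-rank in
(pair, side effect), matching the link-prediction model. Feature
matrices are the latents plus Gaussian noise of scale `noise_sd`.

Defaults (the **standard fixture**): 80 drugs, 25 side effects, rank
k = 8, 400 sampled pairs, `noise_sd` 0.1, `bias` −0.5, `skew` 0.7,
`signal` 3.0, seed 7. The signal scale was set by calibrating the
Bayes-optimal AUROC of the fixture (scoring held-out cells by their true
planted logits) to ≈0.95: strong enough that a correct learner can
demonstrably recover the structure, weak enough that recovery is not
trivial. `bias` −0.5 gives edge density ≈0.3; `skew` > 0 makes the
per-side-effect frequency distribution heavy-tailed (mean above median),
directionally matching real polypharmacy tables. Generated SMILES-like
strings have balanced branches and paired ring digits but are not
guaranteed chemically valid — validity is irrelevant to the embedding
contract.

What the fixture does *not* emulate: the real data's scale (tens of
thousands of pairs, ~10³ side effects), its exact degree spectrum, drug
chemistry (features are planted latents, not molecular descriptors), and
the information gap between chemical structure and biological mechanism.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and can extract planted signal; it says nothing
about predictive performance on real pharmacovigilance data.

## Training presets for the fixture scale

The full-scale defaults (MLP 512/1024/2048, batch 512; GNN dropout 0.8,
lr 0.01) are sized for millions of associations. At fixture scale
(~3×10³ edges, 400 rows) the packaged presets are used instead and are
the package's own scale-appropriate choices: MLP 64/64 hidden, batch 64;
GNN dropout 0.2, lr 5e-4, patience 60, up to 600 epochs. Very high
dropout at this scale starves learning; the gentler rate with long
patience lets the two-layer encoder converge. All experiments in the
tests and the acceptance script run these presets with fixed seeds.

## Known limitations

* The GNN trains full-graph per batch; neighbor sampling for
  million-edge graphs is not implemented (edge mini-batching is).
* Pretrained-LM providers are contract adapters only; no checkpoint
  loading or fine-tuning ships with the package.
* The protocol is strictly transductive — unseen drugs or side effects
  cannot be scored.
* AP@50 on small candidate sets (n < 50) truncates k to n, which inflates
  comparability across differently sized sets; the per-group tables
  report `n` alongside.
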