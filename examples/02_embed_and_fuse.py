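"""Embed SMILES strings and fuse two drug vectors into one pair vector.

Uses the offline hash-ngram encoder (seeded character n-gram feature
hashing); pretrained-LM providers expose the same contract when their
checkpoints are available.
"""

import numpy as np

import polysides as ps

provider = ps.get_provider("hash-ngram", dim=64, seed=0)

# character tokenization as chemical LMs apply it to SMILES
chem = ps.get_provider("chemberta-deepchem")
print("tokens:", list(ps.tokenize(chem, "C(CS(=O)(=O)O)S").tokens))

smiles = ["CCO", "CC(=O)O", "c1ccccc1"]
vectors = provider.encode_batch(smiles)
print(f"embedded {len(smiles)} drugs -> {vectors.shape} (unit-norm rows)")

e1, e2 = vectors[0], vectors[1]
for strategy in ("sum", "mean", "concat", "product"):
    fused = ps.fuse_pair(e1, e2, strategy)
    print(f"{strategy:8s} -> dim {fused.shape[0]}, norm {np.linalg.norm(fused):.3f}")

# sum is the default pair representation (e_pair = e1 + e2); it is
# symmetric in the two drugs, so row order in the pair table cannot
# change the downstream features.
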