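"""Load a raw drug-pair/side-effect table and reshape it for classification.

Builds a small synthetic association table, filters side effects by how
many distinct drug pairs they occur in, and groups the remaining rows into
one multi-label row per unordered pair.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import polysides as ps
from polysides.pipeline import RunConfig, simulate

with TemporaryDirectory() as tmp:
    paths = simulate(RunConfig(seed=7, n_pairs=200), Path(tmp))
    records = ps.load_association_table(paths["associations"])
    print(f"raw associations: {len(records)} rows")

    filtered, vocab = ps.filter_common_side_effects(records, min_pairs=10)
    print(f"side effects in >=10 distinct pairs: {len(vocab)} "
          f"({len(filtered)} rows kept)")

    table = ps.group_to_multilabel(filtered, vocab)
    print(f"multi-label table: {len(table)} pairs x {len(vocab)} side effects")
    print(f"first row: pair {table.pairs[0]} -> {sorted(table.side_effect_sets[0])}")

# The filter counts distinct unordered pairs, not raw rows, so duplicated
# or swapped-order rows never inflate a side effect's support.
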