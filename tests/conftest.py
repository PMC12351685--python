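import numpy as np
import pytest

import polysides as ps


@pytest.fixture()
def toy_records():
    """Small association table: 2 pairs, 3 side effects, one swapped-order row."""
    return [
        ps.AssociationRecord("d1", "d2", "A", "alpha"),
        ps.AssociationRecord("d1", "d2", "B", "beta"),
        ps.AssociationRecord("d2", "d1", "C", "gamma"),
        ps.AssociationRecord("d1", "d3", "A", "alpha"),
        ps.AssociationRecord("d3", "d2", "A", "alpha"),
    ]


@pytest.fixture()
def toy_vocab(toy_records):
    return ps.SideEffectVocabulary.from_records(toy_records)


@pytest.fixture()
def assoc_csv(tmp_path):
    path = tmp_path / "assoc.csv"
    path.write_text(
        "STITCH 1,STITCH 2,Polypharmacy Side Effect,Side Effect Name\n"
        "CID1,CID2,C05,headache\n"
        "CID2,CID1,C06,nausea\n"
        "CID1,CID3,C05,headache\n"
        "CID4,CID4,C05,headache\n"
    )
    return path


@pytest.fixture(scope="session")
def standard_fixture():
    """The reference planted fixture: 80 drugs, 25 side effects, rank 8."""
    return ps.standard_fixture(seed=7)


@pytest.fixture(scope="session")
def standard_graph(standard_fixture):
    table, pair_f, se_f, _ = standard_fixture
    return ps.build_graph(table, pair_f, se_f)


@pytest.fixture(scope="session")
def trained_gnn(standard_graph):
    """GNN trained once on the standard fixture; shared across tests."""
    split = ps.split_edges(standard_graph, seed=7)
    model, log = ps.train_gnn(standard_graph, split, ps.toy_config(seed=7))
    return model, split, log


@pytest.fixture(scope="session")
def trained_mlp(standard_fixture):
    """MLP trained once on the standard fixture's planted features."""
    table, pair_f, _, _ = standard_fixture
    targets = table.multihot
    cfg = ps.toy_mlp_config(output_dim=targets.shape[1], seed=7)
    split = ps.split_rows(len(table), ps.SplitSpec(seed=7))
    model = ps.build_mlp(cfg, pair_f.shape[1])
    model, log = ps.train_mlp(model, pair_f, targets, split, cfg)
    return model, split, log


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
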