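import numpy as np
import pytest

import polysides as ps
from polysides import gnn
from polysides.gnn import BipartiteGraph, ConvLayerParams


def conv_double_loop_oracle(states, message_edges, W1, W2):
    """Brute-force evaluation: per node, self term plus explicit neighbor sum."""
    n = states.shape[0]
    out = np.zeros((n, W1.shape[0]))
    for i in range(n):
        acc = W1 @ states[i]
        for src, dst in message_edges:
            if dst == i:
                acc = acc + W2 @ states[src]
        out[i] = acc
    return out


@pytest.fixture()
def tiny_graph(rng):
    # 2 pairs with side-effect sets {A} and {A, B}
    vocab = ps.SideEffectVocabulary((("A", "a"), ("B", "b")))
    records = [
        ps.AssociationRecord("d1", "d2", "A"),
        ps.AssociationRecord("d1", "d3", "A"),
        ps.AssociationRecord("d1", "d3", "B"),
    ]
    table = ps.group_to_multilabel(records, vocab)
    return ps.build_graph(table, rng.normal(size=(2, 4)), rng.normal(size=(2, 3)))


class TestBuildGraph:
    def test_hand_counted_nodes_and_edges(self, tiny_graph):
        assert tiny_graph.n_pairs == 2 and tiny_graph.n_se == 2
        assert len(tiny_graph.edges) == 3

    def test_empty_table(self):
        vocab = ps.SideEffectVocabulary(())
        table = ps.group_to_multilabel([], vocab)
        g = ps.build_graph(table, np.empty((0, 4)), np.empty((0, 3)))
        assert g.n_nodes == 0 and len(g.edges) == 0

    def test_feature_misalignment_rejected(self, rng):
        vocab = ps.SideEffectVocabulary((("A", "a"),))
        table = ps.group_to_multilabel([ps.AssociationRecord("d1", "d2", "A")], vocab)
        with pytest.raises(ValueError):
            ps.build_graph(table, rng.normal(size=(5, 4)), rng.normal(size=(1, 3)))

    def test_duplicate_edges_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicate"):
            BipartiteGraph(
                edges=np.array([[0, 0], [0, 0]]),
                pair_features=rng.normal(size=(1, 2)),
                se_features=rng.normal(size=(1, 2)),
            )


class TestMakeUndirected:
    def test_doubles_duplicate_free_input(self):
        e = np.array([[0, 5], [1, 5], [2, 6]])
        und = ps.make_undirected(e)
        assert len(und) == 6

    def test_idempotent_as_set_operation(self, rng):
        e = rng.integers(0, 10, size=(12, 2))
        e = np.unique(e, axis=0)
        once = ps.make_undirected(e)
        twice = ps.make_undirected(once)
        assert np.array_equal(once, twice)


class TestSplitEdges:
    @pytest.fixture()
    def graph100(self, rng):
        # exactly 100 edges on a 20x10 bipartite grid
        cells = rng.choice(200, size=100, replace=False)
        edges = np.column_stack([cells // 10, cells % 10])
        return BipartiteGraph(
            edges=edges, pair_features=rng.normal(size=(20, 3)), se_features=rng.normal(size=(10, 3))
        )

    def test_stated_fractions_100_edges(self, graph100):
        split = ps.split_edges(graph100, seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (80, 10, 10)
        assert (len(split.supervision), len(split.message)) == (24, 56)

    def test_positive_sets_disjoint_and_conserved(self, graph100):
        split = ps.split_edges(graph100, seed=3)
        sets = [
            {tuple(e) for e in part}
            for part in (split.supervision, split.message, split.val, split.test)
        ]
        union = set().union(*sets)
        assert sum(len(s) for s in sets) == len(union) == 100
        assert {tuple(e) for e in split.train} == sets[0] | sets[1]

    def test_negatives_disjoint_from_positives(self, graph100):
        split = ps.split_edges(graph100, seed=3)
        pos = {tuple(e) for e in graph100.edges}
        negs = {tuple(e) for e in split.val_negatives} | {tuple(e) for e in split.test_negatives}
        assert not pos & negs
        assert len(split.val_negatives) == len(split.val)
        assert len(split.test_negatives) == len(split.test)

    def test_seed_determinism(self, graph100):
        a = ps.split_edges(graph100, seed=11)
        b = ps.split_edges(graph100, seed=11)
        assert np.array_equal(a.supervision, b.supervision)
        assert np.array_equal(a.test_negatives, b.test_negatives)

    def test_too_few_edges(self, rng):
        g = BipartiteGraph(
            edges=np.array([[0, 0]]),
            pair_features=rng.normal(size=(1, 2)),
            se_features=rng.normal(size=(1, 2)),
        )
        with pytest.raises(ValueError):
            ps.split_edges(g)


class TestSampleNegatives:
    def test_enumerated_complement_2x2(self, rng):
        g = BipartiteGraph(
            edges=np.array([[0, 0]]),
            pair_features=rng.normal(size=(2, 2)),
            se_features=rng.normal(size=(2, 2)),
        )
        for seed in range(20):
            neg = ps.sample_negative_edges(g, 3, seed=seed)
            assert len(neg) == 3
            assert {tuple(e) for e in neg} == {(0, 1), (1, 0), (1, 1)}

    def test_complete_bipartite_has_empty_complement(self, rng):
        g = BipartiteGraph(
            edges=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
            pair_features=rng.normal(size=(2, 2)),
            se_features=rng.normal(size=(2, 2)),
        )
        with pytest.raises(ValueError):
            ps.sample_negative_edges(g, 1)

    def test_never_intersects_positives_over_many_draws(self, standard_graph):
        pos = {tuple(e) for e in standard_graph.edges}
        for seed in range(1000):
            neg = ps.sample_negative_edges(standard_graph, 20, seed=seed)
            assert len(neg) == 20
            assert not pos & {tuple(e) for e in neg}


class TestConvForward:
    def test_star_graph_hand_example(self):
        # center node 0 with h=[0]; leaves [1], [2], [3] all message to it
        states = np.array([[0.0], [1.0], [2.0], [3.0]])
        edges = np.array([[1, 0], [2, 0], [3, 0]])
        params = ConvLayerParams(W1=np.eye(1), W2=np.eye(1))
        out = ps.conv_forward(states, edges, params)
        assert out[0, 0] == pytest.approx(6.0)

    def test_isolated_node_gets_self_term_only(self, rng):
        W1, W2 = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        states = rng.normal(size=(4, 2))
        edges = np.array([[0, 1]])
        out = ps.conv_forward(states, edges, ConvLayerParams(W1, W2))
        for i in (0, 2, 3):  # no incoming messages
            assert np.allclose(out[i], W1 @ states[i])

    def test_zero_neighbor_weight_reduces_to_linear_map(self, rng):
        W1 = rng.normal(size=(3, 3))
        states = rng.normal(size=(5, 3))
        edges = rng.integers(0, 5, size=(8, 2))
        out = ps.conv_forward(states, edges, ConvLayerParams(W1, np.zeros((3, 3))))
        assert np.allclose(out, states @ W1.T)

    def test_matches_double_loop_oracle_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 31))
            d_in, d_out = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            states = rng.normal(size=(n, d_in))
            n_edges = int(rng.integers(0, 3 * n))
            edges = rng.integers(0, n, size=(n_edges, 2))
            W1, W2 = rng.normal(size=(d_out, d_in)), rng.normal(size=(d_out, d_in))
            ours = ps.conv_forward(states, edges, ConvLayerParams(W1, W2))
            oracle = conv_double_loop_oracle(states, edges, W1, W2)
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_permutation_invariance(self, rng):
        n = 12
        states = rng.normal(size=(n, 4))
        edges = rng.integers(0, n, size=(20, 2))
        W = ConvLayerParams(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        perm = rng.permutation(n)
        out = ps.conv_forward(states, edges, W)
        inv = np.argsort(perm)
        out_perm = ps.conv_forward(states[perm], inv[edges], W)
        assert np.allclose(out[perm], out_perm, atol=1e-10)


class TestDecodeScore:
    def test_values_and_symmetry(self):
        assert ps.decode_score([1, 0], [0, 1]) == 0.0
        assert ps.decode_score([1, 2], [3, 4]) == 11.0
        assert ps.decode_score([3, 4], [1, 2]) == 11.0

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            ps.decode_score([1, 2], [1, 2, 3])


class TestInitNodeStates:
    def test_zero_features_leave_id_embeddings(self, tiny_graph, rng):
        d = 5
        ids = rng.normal(size=(tiny_graph.n_nodes, d))
        zero_graph = BipartiteGraph(
            edges=tiny_graph.edges,
            pair_features=np.zeros_like(tiny_graph.pair_features),
            se_features=np.zeros_like(tiny_graph.se_features),
        )
        states = gnn.init_node_states(
            zero_graph, ids, (rng.normal(size=(d, 4)), np.zeros(d)),
            (rng.normal(size=(d, 3)), np.zeros(d)),
        )
        assert np.allclose(states, ids)

    def test_identical_features_distinct_ids_distinct_states(self, rng):
        g = BipartiteGraph(
            edges=np.array([[0, 0]]),
            pair_features=np.ones((2, 4)),
            se_features=np.ones((1, 3)),
        )
        ids = rng.normal(size=(3, 5))
        states = gnn.init_node_states(
            g, ids, (rng.normal(size=(5, 4)), np.zeros(5)), (rng.normal(size=(5, 3)), np.zeros(5))
        )
        assert not np.allclose(states[0], states[1])

    def test_projection_handles_wide_features(self, rng):
        # e.g. substructure embeddings of width 300 projected to 64
        g = BipartiteGraph(
            edges=np.array([[0, 0]]),
            pair_features=rng.normal(size=(1, 300)),
            se_features=rng.normal(size=(1, 768)),
        )
        states = gnn.init_node_states(
            g,
            np.zeros((2, 64)),
            (rng.normal(size=(64, 300)), np.zeros(64)),
            (rng.normal(size=(64, 768)), np.zeros(64)),
        )
        assert states.shape == (2, 64)


class TestTrainingSanity:
    def test_training_positive_scores_high_on_toy_graph(self, rng):
        cells = rng.choice(30, size=12, replace=False)
        edges = np.column_stack([cells // 5, cells % 5])
        g = BipartiteGraph(
            edges=edges,
            pair_features=rng.normal(size=(6, 3)),
            se_features=rng.normal(size=(5, 3)),
        )
        split = ps.split_edges(g, seed=0)
        cfg = gnn.GNNConfig(seed=0, dropout=0.0, lr=0.01, max_epochs=150, patience=150)
        model, _ = ps.train_gnn(g, split, cfg)
        logits = ps.predict_links(model, g, split.supervision, split.message)
        from scipy.special import expit

        assert expit(logits).mean() > 0.5

    def test_duplicate_queries_duplicate_scores(self, trained_gnn, standard_graph):
        model, split, _ = trained_gnn
        q = np.vstack([split.test[:1], split.test[:1]])
        s = ps.predict_links(model, standard_graph, q, split.train)
        assert s[0] == s[1]

    def test_unknown_node_rejected(self, trained_gnn, standard_graph):
        model, split, _ = trained_gnn
        bad = np.array([[standard_graph.n_pairs + 5, 0]])
        with pytest.raises(ValueError, match="transductive"):
            ps.predict_links(model, standard_graph, bad, split.train)

    def test_training_is_seed_deterministic(self, rng):
        cells = rng.choice(60, size=25, replace=False)
        edges = np.column_stack([cells // 6, cells % 6])
        g = BipartiteGraph(
            edges=edges,
            pair_features=rng.normal(size=(10, 3)),
            se_features=rng.normal(size=(6, 3)),
        )
        split = ps.split_edges(g, seed=4)
        cfg = gnn.GNNConfig(seed=4, dropout=0.2, max_epochs=20, patience=20)
        m1, log1 = ps.train_gnn(g, split, cfg)
        m2, log2 = ps.train_gnn(g, split, cfg)
        assert log1 == log2
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
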