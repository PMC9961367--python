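"""Propagation operator, GCN forward pass, transductive training."""
import numpy as np
import pytest

import popgraph_stager as pg
from popgraph_stager.containers import PopulationGraph
from popgraph_stager.gcn import GCNModel, init_model, node_features


def _masks(n, n_train, n_val):
    masks = {"train": np.zeros(n, bool), "val": np.zeros(n, bool),
             "test": np.zeros(n, bool)}
    masks["train"][:n_train] = True
    masks["val"][n_train:n_train + n_val] = True
    masks["test"][n_train + n_val:] = True
    return masks


class TestNormalizeAdjacency:
    def test_empty_graph_gives_identity(self):
        op = pg.normalize_adjacency(np.zeros((5, 5)))
        assert np.allclose(op.S, np.eye(5))

    def test_two_node_hand_value(self):
        op = pg.normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(op.S, [[0.5, 0.5], [0.5, 0.5]])

    def test_matches_entrywise_brute_force(self, rng):
        for n in (3, 6, 10):
            M = rng.uniform(0, 2, size=(n, n))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 0.0)
            S = pg.normalize_adjacency(A).S
            A_hat = A + np.eye(n)
            d = A_hat.sum(axis=1)
            oracle = np.array([[A_hat[i, j] / np.sqrt(d[i] * d[j])
                                for j in range(n)] for i in range(n)])
            assert np.allclose(S, oracle, atol=1e-10)

    def test_spectral_radius_at_most_one(self, rng):
        M = rng.uniform(0, 3, size=(8, 8))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0.0)
        S = pg.normalize_adjacency(A).S
        assert np.abs(np.linalg.eigvalsh(S)).max() <= 1 + 1e-10

    def test_stronger_edge_increases_coupling(self):
        s_weak = pg.normalize_adjacency(np.array([[0, 0.2], [0.2, 0]])).S
        s_strong = pg.normalize_adjacency(np.array([[0, 2.0], [2.0, 0]])).S
        assert s_strong[0, 1] > s_weak[0, 1]

    def test_rejects_invalid_adjacency(self):
        with pytest.raises(ValueError):
            pg.normalize_adjacency(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            pg.normalize_adjacency(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestForward:
    def test_rows_sum_to_one(self, rng):
        cfg = pg.GCNConfig(hidden_units=4, n_classes=3, seed=0)
        model = init_model(6, cfg)
        A = np.abs(rng.normal(size=(5, 5)))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        probs = pg.forward(model, pg.normalize_adjacency(A),
                           rng.normal(size=(5, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identity_operator_degenerates_to_mlp(self):
        cfg = pg.GCNConfig(hidden_units=3, n_classes=2, dropout=0.0, seed=0)
        model = init_model(3, cfg)
        model.W0 = np.eye(3)
        model.b0 = np.zeros(3)
        X = np.array([[1.0, -2.0, 0.5], [-1.0, 3.0, -0.2]])
        probs = pg.forward(model, np.eye(2), X)
        relu_x = np.maximum(X, 0)
        expected_z2 = relu_x @ model.W1 + model.b1
        e = np.exp(expected_z2 - expected_z2.max(axis=1, keepdims=True))
        assert np.allclose(probs, e / e.sum(axis=1, keepdims=True))

    def test_two_node_hand_computed_fixture(self):
        cfg = pg.GCNConfig(hidden_units=2, n_classes=2, dropout=0.0, seed=0)
        model = GCNModel(W0=np.array([[1.0, -1.0], [0.5, 0.0]]),
                         b0=np.array([0.1, -0.2]),
                         W1=np.array([[1.0, 0.0], [-1.0, 1.0]]),
                         b1=np.array([0.0, 0.3]), config=cfg)
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        # scalar arithmetic: SX rows are both (2, 3);
        # z1 = (2 + 1.5 + 0.1, -2 - 0.2) = (3.6, -2.2) -> h1 = (3.6, 0)
        # z2 = (3.6, 0.3); softmax
        e = np.exp([3.6, 0.3] - np.max([3.6, 0.3]))
        expected = e / e.sum()
        probs = pg.forward(model, S, X)
        assert np.allclose(probs, np.vstack([expected, expected]), atol=1e-12)

    def test_nonfinite_activation_raises(self):
        cfg = pg.GCNConfig(hidden_units=2, n_classes=2, dropout=0.0, seed=0)
        model = init_model(2, cfg)
        model.W1 = model.W1 * np.inf
        with pytest.raises(FloatingPointError):
            pg.forward(model, np.eye(2), np.ones((2, 2)))

    def test_permutation_equivariance(self, rng):
        cfg = pg.GCNConfig(hidden_units=4, n_classes=2, dropout=0.0, seed=3)
        model = init_model(5, cfg)
        n = 7
        M = np.abs(rng.normal(size=(n, n)))
        A = (M + M.T) / 2
        np.fill_diagonal(A, 0)
        X = rng.normal(size=(n, 5))
        probs = pg.forward(model, pg.normalize_adjacency(A), X)
        perm = rng.permutation(n)
        probs_p = pg.forward(
            model, pg.normalize_adjacency(A[np.ix_(perm, perm)]), X[perm])
        assert np.allclose(probs_p, probs[perm], atol=1e-10)


def _clique_graph(n_per_class=12, sep=6.0, seed=0):
    """Two same-class cliques with no inter-clique edges, strong features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    A = np.zeros((n, n))
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        A[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(A, 0.0)
    X = rng.normal(size=(n, 8)) + sep * np.outer(labels, np.ones(8))
    order = rng.permutation(n)  # interleave classes across the split
    masks = {"train": np.zeros(n, bool), "val": np.zeros(n, bool),
             "test": np.zeros(n, bool)}
    masks["train"][order[: n // 2]] = True
    masks["val"][order[n // 2: 3 * n // 4]] = True
    masks["test"][order[3 * n // 4:]] = True
    graph = PopulationGraph(ids=[f"n{i}" for i in range(n)], A=A, X=X,
                            masks=masks)
    return graph, labels


class TestTraining:
    def test_separable_cliques_reach_perfect_test_accuracy(self):
        graph, labels = _clique_graph()
        # oracle check first: nearest centroid on raw features is perfect
        tr = graph.masks["train"]
        cents = [graph.X[tr & (labels == c)].mean(axis=0) for c in (0, 1)]
        nc = np.array([np.argmin([np.linalg.norm(x - c) for c in cents])
                       for x in graph.X])
        assert np.array_equal(nc, labels)
        model, _ = pg.train_transductive(
            graph, labels, pg.GCNConfig(seed=1, learning_rate=3e-3))
        pred, _ = pg.predict(model, graph)
        test = graph.masks["test"]
        assert np.mean(pred[test] == labels[test]) == 1.0

    def test_same_seed_reproduces_history_and_weights(self):
        graph, labels = _clique_graph(seed=2)
        cfg = pg.GCNConfig(seed=7)
        m1, h1 = pg.train_transductive(graph, labels, cfg)
        m2, h2 = pg.train_transductive(graph, labels, cfg)
        assert h1.equals(h2)
        assert np.array_equal(m1.W0, m2.W0) and np.array_equal(m1.W1, m2.W1)

    def test_zero_patience_stops_at_first_non_improving_epoch(self):
        graph, labels = _clique_graph(seed=3)
        cfg = pg.GCNConfig(seed=0, patience=0, max_epochs=100)
        _, history = pg.train_transductive(graph, labels, cfg)
        val = history["val_acc"].to_numpy()
        # every epoch except the last strictly improved on the running best
        running = -np.inf
        for acc in val[:-1]:
            assert acc > running
            running = acc
        assert val[-1] <= running

    def test_training_never_exceeds_max_epochs(self):
        graph, labels = _clique_graph(seed=4)
        cfg = pg.GCNConfig(seed=0, max_epochs=5, patience=50)
        _, history = pg.train_transductive(graph, labels, cfg)
        assert len(history) <= 5

    def test_missing_class_in_train_mask_is_reported(self):
        graph, labels = _clique_graph(seed=5)
        bad = labels.copy()
        bad[graph.masks["train"]] = 0
        with pytest.raises(ValueError, match="1"):
            pg.train_transductive(graph, bad, pg.GCNConfig(seed=0))

    def test_loss_decreases_on_separable_problem(self):
        graph, labels = _clique_graph(seed=6)
        cfg = pg.GCNConfig(seed=0, dropout=0.0, learning_rate=3e-3)
        _, history = pg.train_transductive(graph, labels, cfg)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]


class TestPredict:
    def test_probabilities_argmax_and_tie_break(self):
        cfg = pg.GCNConfig(hidden_units=2, n_classes=2, dropout=0.0, seed=0,
                           standardize_features=False)
        # zero weights -> uniform probabilities -> tie -> class 0
        model = GCNModel(W0=np.zeros((3, 2)), b0=np.zeros(2),
                         W1=np.zeros((2, 2)), b1=np.zeros(2), config=cfg)
        graph = PopulationGraph(ids=["a", "b"], A=np.zeros((2, 2)),
                                X=np.ones((2, 3)), masks=_masks(2, 1, 1))
        pred, probs = pg.predict(model, graph)
        assert np.allclose(probs, 0.5)
        assert np.array_equal(pred, [0, 0])

    def test_predict_consistent_with_forward(self):
        graph, labels = _clique_graph(seed=8)
        model, _ = pg.train_transductive(graph, labels, pg.GCNConfig(seed=2))
        pred, probs = pg.predict(model, graph)
        direct = pg.forward(model, pg.normalize_adjacency(graph.A),
                            node_features(graph, model.config))
        assert np.allclose(probs, direct)
        assert np.array_equal(pred, direct.argmax(axis=1))

    def test_checkpoint_round_trip(self, tmp_path):
        graph, labels = _clique_graph(seed=9)
        model, _ = pg.train_transductive(graph, labels, pg.GCNConfig(seed=3))
        path = tmp_path / "gcn.npz"
        model.save(path)
        back = GCNModel.load(path)
        p1, _ = pg.predict(model, graph)
        p2, _ = pg.predict(back, graph)
        assert np.array_equal(p1, p2)
        assert back.config == model.config
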