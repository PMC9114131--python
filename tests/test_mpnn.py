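import numpy as np
import pytest

from molbias.autodiff import Tensor
from molbias.molgraph import BOND_TYPES, MolecularGraph
from molbias.mpnn import (
    MPNN,
    GraphBatch,
    MPNNConfig,
    TrainConfig,
    gru_update,
    message_pass,
    train,
    weighted_mse,
)
from molbias.synthetic import GeneratorConfig, PropertySpec, attach_property, generate_population

from conftest import ATOMS


def _batch(graphs):
    return GraphBatch(graphs, ATOMS, BOND_TYPES)


def _identity_params(D):
    params = {}
    for b in BOND_TYPES:
        params[f"msg_W.{b}"] = Tensor(np.eye(D))
    return params


class TestMessagePass:
    def test_isolated_node_gets_zero_message(self):
        g = MolecularGraph("g", ["C"], [])
        batch = _batch([g])
        h = Tensor(np.ones((1, 4)))
        m = message_pass(h, batch, _identity_params(4))
        assert np.allclose(m.data, 0.0)

    def test_identity_weight_copies_neighbor(self):
        g = MolecularGraph("g", ["C", "N"], [(0, 1, "single")])
        batch = _batch([g])
        h = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
        m = message_pass(h, batch, _identity_params(2))
        # nonnegative states + identity weights: each node receives its neighbor
        assert np.allclose(m.data, [[3.0, 4.0], [1.0, 2.0]])

    def test_two_node_graph_matches_hand_linear_algebra(self):
        rng = np.random.default_rng(0)
        D = 3
        W = rng.normal(size=(D, D))
        params = {f"msg_W.{b}": Tensor(W) for b in BOND_TYPES}
        g = MolecularGraph("g", ["C", "O"], [(0, 1, "double")])
        h = rng.normal(size=(2, D))
        m = message_pass(Tensor(h), _batch([g]), params)
        expected = np.maximum(np.vstack([h[1] @ W, h[0] @ W]), 0.0)
        assert np.allclose(m.data, expected, atol=1e-6)


class TestGRUUpdate:
    def test_zero_everything_is_fixed_point(self):
        rng = np.random.default_rng(1)
        D = 4
        params = {}
        for gate in ("z", "r", "n"):
            params[f"gru_W{gate}"] = Tensor(rng.normal(size=(D, D)))
            params[f"gru_U{gate}"] = Tensor(rng.normal(size=(D, D)))
            params[f"gru_b{gate}"] = Tensor(np.zeros(D))
        out = gru_update(Tensor(np.zeros((2, D))), Tensor(np.zeros((2, D))), params)
        assert np.allclose(out.data, 0.0)

    def test_matches_reference_gru_cell(self):
        """Independent numpy transcription of the standard GRU equations."""
        rng = np.random.default_rng(2)
        D = 5
        params = {}
        for gate in ("z", "r", "n"):
            params[f"gru_W{gate}"] = Tensor(rng.normal(size=(D, D)))
            params[f"gru_U{gate}"] = Tensor(rng.normal(size=(D, D)))
            params[f"gru_b{gate}"] = Tensor(rng.normal(size=D))
        h = rng.normal(size=(3, D))
        m = rng.normal(size=(3, D))

        def sig(x):
            return 1 / (1 + np.exp(-x))

        z = sig(m @ params["gru_Wz"].data + h @ params["gru_Uz"].data + params["gru_bz"].data)
        r = sig(m @ params["gru_Wr"].data + h @ params["gru_Ur"].data + params["gru_br"].data)
        n = np.tanh(m @ params["gru_Wn"].data + (r * h) @ params["gru_Un"].data + params["gru_bn"].data)
        expected = (1 - z) * n + z * h
        out = gru_update(Tensor(h), Tensor(m), params)
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_output_shape(self):
        D = 4
        params = {
            f"gru_{k}{g}": Tensor(np.zeros((D, D)) if k in "WU" else np.zeros(D))
            for g in ("z", "r", "n")
            for k in ("W", "U", "b")
        }
        out = gru_update(Tensor(np.zeros((7, D))), Tensor(np.zeros((7, D))), params)
        assert out.shape == (7, D)


def _permute_graph(g: MolecularGraph, perm) -> MolecularGraph:
    inv = {old: new for new, old in enumerate(perm)}
    nodes = [g.nodes[old] for old in perm]
    edges = []
    for u, v, b in g.edges:
        a, c = inv[u], inv[v]
        edges.append((min(a, c), max(a, c), b))
    return MolecularGraph(id=g.id + "_perm", nodes=nodes, edges=sorted(edges))


class TestReadoutAndForward:
    @pytest.fixture(scope="class")
    def model(self):
        return MPNN(MPNNConfig(n_layers=2, hidden_dim=8, set2set_steps=2), ATOMS, BOND_TYPES, seed=0)

    def test_permutation_invariance(self, model):
        ds = generate_population(GeneratorConfig(n_molecules=10, size_range=(4, 9), seed=5))
        rng = np.random.default_rng(0)
        base = model.predict(ds.graphs)
        for _ in range(30):
            k = rng.integers(0, len(ds.graphs))
            g = ds.graphs[k]
            perm = rng.permutation(g.n_atoms)
            out = model.predict([_permute_graph(g, perm)])
            assert out[0] == pytest.approx(base[k], abs=1e-6)

    def test_classification_output_in_unit_interval(self):
        m = MPNN(MPNNConfig(n_layers=1, hidden_dim=6, head="binary_classification"), ATOMS, BOND_TYPES, seed=1)
        ds = generate_population(GeneratorConfig(n_molecules=20, seed=2))
        p = m.predict(ds.graphs)
        assert np.all((p > 0) & (p < 1))

    def test_forward_deterministic(self, model):
        ds = generate_population(GeneratorConfig(n_molecules=5, seed=3))
        assert np.array_equal(model.predict(ds.graphs), model.predict(ds.graphs))

    def test_single_node_graph_matches_hand_computation(self, model):
        """For one node the attention weight is 1, so the readout r equals the
        node's trunk state; replicate the whole set2set recurrence by hand."""
        g = MolecularGraph("g", ["N"], [])
        batch = model.batch([g])
        h = model.node_states(batch).data  # (1, D)
        D = h.shape[1]
        p = model.params

        def sig(x):
            return 1 / (1 + np.exp(-x))

        q = np.zeros((1, D))
        c = np.zeros((1, D))
        q_star = np.zeros((1, 2 * D))
        for _ in range(model.config.set2set_steps):
            gates = q_star @ p["head.lstm_W"].data + q @ p["head.lstm_U"].data + p["head.lstm_b"].data
            i, f, gg, o = np.split(gates, 4, axis=1)
            c = sig(f) * c + sig(i) * np.tanh(gg)
            q = sig(o) * np.tanh(c)
            q_star = np.concatenate([q, h], axis=1)  # attention over one node -> r = h
        hidden = np.maximum(q_star @ p["head.lin1_W"].data + p["head.lin1_b"].data, 0)
        expected = (hidden @ p["head.lin2_W"].data + p["head.lin2_b"].data)[0, 0]
        got = model.forward(batch).data[0, 0]
        assert got == pytest.approx(expected, abs=1e-9)


class TestTraining:
    def test_unit_weights_equal_unweighted_objective(self):
        rng = np.random.default_rng(0)
        pred = Tensor(rng.normal(size=(6, 1)))
        y = rng.normal(size=6)
        ones = weighted_mse(pred, y, np.ones(6))
        assert float(ones.data) == pytest.approx(float(np.mean((pred.data[:, 0] - y) ** 2)))

    def test_learns_noiseless_size_target(self):
        ds = generate_population(GeneratorConfig(n_molecules=200, size_range=(3, 15), seed=4))
        attach_property(ds, PropertySpec("y", {"mean_degree": 3.0}), seed=0)
        y = ds.target("y")
        model = MPNN(MPNNConfig(n_layers=2, hidden_dim=12, set2set_steps=2), ds.atom_vocab, ds.bond_vocab, seed=0)
        cfg = TrainConfig(initial_lr=5e-3, max_epochs=30, min_lr=1e-6, seed=0)
        model, hist = train(model, ds.graphs, y, cfg)
        pred = model.predict(ds.graphs)
        mean_mae = np.mean(np.abs(y - y.mean()))
        assert np.mean(np.abs(pred - y)) < mean_mae
        # argmin contract: returned params achieved the best validation loss
        assert hist.best_val_loss <= hist.val_loss[-1] + 1e-12
        # loss trend: smoothed early epochs above smoothed late epochs
        assert np.mean(hist.train_loss[:5]) > np.mean(hist.train_loss[-5:])

    def test_nonfinite_loss_aborts(self):
        ds = generate_population(GeneratorConfig(n_molecules=12, seed=6))
        y = np.full(12, 1.0)
        model = MPNN(MPNNConfig(n_layers=1, hidden_dim=4), ds.atom_vocab, ds.bond_vocab, seed=0)
        model.params["embed_W"].data[:] = np.inf
        with pytest.raises(FloatingPointError):
            train(model, ds.graphs, y, TrainConfig(max_epochs=1, seed=0))

    def test_weight_length_mismatch_rejected(self):
        ds = generate_population(GeneratorConfig(n_molecules=8, seed=6))
        model = MPNN(MPNNConfig(n_layers=1, hidden_dim=4), ds.atom_vocab, ds.bond_vocab, seed=0)
        with pytest.raises(ValueError):
            train(model, ds.graphs, np.zeros(8), TrainConfig(max_epochs=1), weights=np.ones(3))
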