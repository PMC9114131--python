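import itertools

import numpy as np
import pytest

from molbias.autodiff import Tensor
from molbias.cfr import (
    CFRBatch,
    CFRModel,
    cfr_losses,
    importance_weight,
    importance_weights,
    ipm_wasserstein,
    predict,
    train_cfr,
)
from molbias.mpnn import MPNN, MPNNConfig, TrainConfig, train, weighted_mse
from molbias.synthetic import GeneratorConfig, PropertySpec, attach_property, generate_population

CFG = MPNNConfig(n_layers=1, hidden_dim=6, set2set_steps=2)


def _tiny_dataset(n=12, seed=0):
    ds = generate_population(GeneratorConfig(n_molecules=n, size_range=(3, 7), seed=seed))
    attach_property(ds, PropertySpec("y", {"mean_degree": 2.0}, noise_sd=0.1), seed=1)
    return ds


class TestImportanceWeight:
    def test_symmetric_scores_give_two(self):
        assert importance_weight(np.zeros(2), 1) == pytest.approx(2.0)
        assert importance_weight(np.zeros(2), 0) == pytest.approx(2.0)

    def test_softmax_oracle_ln3(self):
        # Pr(d=1 | phi=(ln 3, 0)) = 1/4, so w = 4
        assert importance_weight(np.array([np.log(3.0), 0.0]), 1) == pytest.approx(4.0)

    def test_reciprocal_softmax_identity(self, rng):
        phi = rng.normal(scale=5.0, size=(10_000, 2))
        for d in (0, 1):
            w = importance_weights(phi, d=d)
            p = np.exp(phi[:, d]) / np.exp(phi).sum(axis=1)
            assert np.max(np.abs(w * p - 1.0)) < 1e-9

    def test_weight_at_least_one(self, rng):
        phi = rng.normal(scale=50.0, size=(1000, 2))
        assert np.all(importance_weights(phi, d=1) >= 1.0)

    def test_overflow_guarded(self):
        w = importance_weight(np.array([1e6, -1e6]), 0)
        assert np.isfinite(w)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            importance_weight(np.array([np.nan, 0.0]), 1)
        with pytest.raises(ValueError):
            importance_weight(np.zeros(2), 2)


def _brute_force_w1(a: np.ndarray, b: np.ndarray) -> float:
    """Exact OT for equal-size uniform clouds: best assignment over all
    permutations (an optimal vertex of the Birkhoff polytope)."""
    n = len(a)
    C = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return min(sum(C[i, p[i]] for i in range(n)) / n for p in itertools.permutations(range(n)))


class TestWasserstein:
    def test_identical_clouds_zero(self, rng):
        z = rng.normal(size=(5, 3))
        assert ipm_wasserstein(z, z, method="exact") == pytest.approx(0.0, abs=1e-8)

    def test_point_masses_closed_form(self):
        assert ipm_wasserstein(np.array([[0.0]]), np.array([[1.0]]), method="exact") == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self, rng):
        a, b = rng.normal(size=(4, 2)), rng.normal(size=(6, 2))
        d_ab = ipm_wasserstein(a, b, method="exact")
        d_ba = ipm_wasserstein(b, a, method="exact")
        assert d_ab == pytest.approx(d_ba, abs=1e-8)
        assert d_ab > 0

    def test_matches_brute_force_assignment_oracle(self, rng):
        for n in (3, 5, 6):
            a, b = rng.normal(size=(n, 2)), rng.normal(size=(n, 2))
            assert ipm_wasserstein(a, b, method="exact") == pytest.approx(_brute_force_w1(a, b), abs=1e-6)

    def test_sinkhorn_approaches_exact(self, rng):
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        exact = ipm_wasserstein(a, b, method="exact")
        approx = ipm_wasserstein(a, b, method="sinkhorn", reg=0.005, n_iter=20_000)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_gradient_flows_through_cost(self):
        a = Tensor(np.array([[0.0, 0.0], [1.0, 1.0]]), requires_grad=True)
        b = Tensor(np.array([[2.0, 0.0], [3.0, 1.0]]))
        d = ipm_wasserstein(a, b, method="sinkhorn", reg=0.01)
        d.backward()
        assert a.grad is not None and np.abs(a.grad).sum() > 0

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            ipm_wasserstein(np.zeros((0, 2)), np.zeros((3, 2)))


class TestCfrLosses:
    @pytest.fixture()
    def setup(self):
        ds = _tiny_dataset()
        model = CFRModel(CFG, ds.atom_vocab, ds.bond_vocab, seed=0, alpha=1.0)
        graphs = ds.graphs
        domains = np.array([1] * 6 + [0] * 6)
        y = ds.target("y")
        return model, CFRBatch(graphs=graphs, domains=domains, y=y)

    def test_zeroed_weight_head_doubles_mse(self, setup):
        model, batch = setup
        model.weight_head["weight.lin2_W"].data[:] = 0.0
        model.weight_head["weight.lin2_b"].data[:] = 0.0
        o_prop, _, _ = cfr_losses(batch, model)
        gb = model.batch(batch.graphs)
        h = model.features(gb)
        pred = model.label_output(h, gb).data[:6, 0]
        mse = np.mean((pred - batch.y[:6]) ** 2)
        assert float(o_prop.data) == pytest.approx(2.0 * mse, rel=1e-9)

    def test_identical_clouds_zero_ipm(self, setup):
        model, _ = setup
        ds = _tiny_dataset()
        graphs = ds.graphs[:4] + ds.graphs[:4]  # same molecules in both domains
        batch = CFRBatch(graphs=graphs, domains=np.array([1] * 4 + [0] * 4), y=np.zeros(8))
        _, o_ipm, _ = cfr_losses(batch, model, ipm_method="exact")
        assert float(o_ipm.data) == pytest.approx(0.0, abs=1e-8)

    def test_confident_correct_domain_scores_vanishing_loss(self, setup):
        model, batch = setup

        class Confident(CFRModel):
            def weight_scores(self, h, gb):
                phi = np.zeros((gb.n_graphs, 2))
                phi[np.arange(gb.n_graphs), batch.domains] = 50.0
                return Tensor(phi)

        model.__class__ = Confident
        _, _, o_dom = cfr_losses(batch, model)
        assert float(o_dom.data) == pytest.approx(0.0, abs=1e-12)

    def test_unlabeled_batch_rejected(self, setup):
        model, batch = setup
        bad = CFRBatch(graphs=batch.graphs, domains=np.zeros(len(batch.graphs), dtype=int), y=batch.y)
        with pytest.raises(ValueError, match="no labeled"):
            cfr_losses(bad, model)

    def test_step_a_never_touches_weight_head(self, setup):
        model, batch = setup
        o_prop, o_ipm, _ = cfr_losses(batch, model)
        (o_prop + model.alpha * o_ipm).backward()
        assert all(p.grad is None for p in model.weight_head.values())
        assert any(p.grad is not None for p in model.trunk.values())

    def test_step_b_never_touches_trunk_or_label_head(self, setup):
        model, batch = setup
        _, _, o_dom = cfr_losses(batch, model)
        o_dom.backward()
        assert all(p.grad is None for p in model.trunk.values())
        assert all(p.grad is None for p in model.label_head.values())
        assert any(p.grad is not None for p in model.weight_head.values())


class TestReductionToBaseline:
    def test_zero_alpha_frozen_weights_give_twice_baseline_gradient(self):
        """With f_W pinned at zero scores every w_i = 2, so the property
        gradient is exactly twice the plain-MSE gradient through the
        same network; verified analytically and by finite differences."""
        ds = _tiny_dataset()
        model = CFRModel(CFG, ds.atom_vocab, ds.bond_vocab, seed=3, alpha=0.0)
        model.weight_head["weight.lin2_W"].data[:] = 0.0
        model.weight_head["weight.lin2_b"].data[:] = 0.0
        y = ds.target("y")
        batch = CFRBatch(graphs=ds.graphs, domains=np.ones(len(ds), dtype=int), y=y)

        def mse_loss():
            gb = model.batch(ds.graphs)
            h = model.features(gb)
            pred = model.label_output(h, gb)
            resid = pred - Tensor(y.reshape(-1, 1))
            return (resid * resid).mean()

        o_prop, _, _ = cfr_losses(batch, model)
        params = {**model.trunk, **model.label_head}
        for p in params.values():
            p.grad = None
        o_prop.backward()
        grads_cfr = {k: p.grad.copy() for k, p in params.items()}

        for p in params.values():
            p.grad = None
        mse_loss().backward()
        for k, p in params.items():
            assert np.allclose(grads_cfr[k], 2.0 * p.grad, atol=1e-9), k

        # finite-difference spot check on one trunk parameter
        key = "embed_W"
        idx = (0, 0)
        eps = 1e-6
        orig = params[key].data[idx]
        params[key].data[idx] = orig + eps
        hi = float(cfr_losses(batch, model)[0].data)
        params[key].data[idx] = orig - eps
        lo = float(cfr_losses(batch, model)[0].data)
        params[key].data[idx] = orig
        assert grads_cfr[key][idx] == pytest.approx((hi - lo) / (2 * eps), abs=1e-4)


class TestTrainAndPredict:
    def test_training_runs_and_predicts_deterministically(self):
        ds = _tiny_dataset(n=20)
        y = ds.target("y")
        model, hist = train_cfr(
            ds.graphs[:12], y[:12], ds.graphs[12:], CFG,
            TrainConfig(initial_lr=1e-2, max_epochs=3, seed=0),
            alpha=10.0, atom_vocab=ds.atom_vocab, bond_vocab=ds.bond_vocab,
        )
        assert len(hist["train_loss"]) == 3
        p1 = predict(model, ds.graphs[12:])
        p2 = predict(model, ds.graphs[12:])
        assert np.array_equal(p1, p2)

    def test_predict_is_label_path_composition(self):
        ds = _tiny_dataset(n=8)
        model = CFRModel(CFG, ds.atom_vocab, ds.bond_vocab, seed=1)
        model.y_mean, model.y_std = 2.0, 3.0
        gb = model.batch(ds.graphs)
        manual = model.label_output(model.features(gb), gb).data[:, 0] * 3.0 + 2.0
        assert np.allclose(predict(model, ds.graphs), manual)

    def test_negative_alpha_rejected(self):
        ds = _tiny_dataset(n=4)
        with pytest.raises(ValueError):
            CFRModel(CFG, ds.atom_vocab, ds.bond_vocab, alpha=-1.0)
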