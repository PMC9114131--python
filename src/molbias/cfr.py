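"""Counterfactual-regression bias correction (end-to-end).

One network, three paths sharing a feature extractor f_F (the
message-passing trunk, no readout):

* label path   f_L(f_F(G)) — set2set readout + regression head, trained
  only on labeled (biased-training-domain) molecules with importance
  weights w_i;
* IPM path — mean-pooled graph embeddings of a mixed batch, split by
  domain, scored by a Wasserstein optimal-transport distance that the
  trunk learns to shrink (domain-invariant representation);
* weight path  f_W(f_F(G)) — a second readout producing two domain
  scores phi; softmax of phi estimates the domain membership
  probability, and w_i = 1 / Pr(d_i | G_i) = 1 + exp(phi^(1-d) - phi^(d))
  is the closed-form importance weight (d fixed to 1 for the labeled
  path, since only training-domain molecules carry labels).

Training alternates per mini-batch: step A minimizes
o_property + alpha * o_ipm over f_F, f_L with f_W frozen (its scores
enter the weights as constants); step B minimizes the domain
cross-entropy o_domain over f_W alone. The deliverable predictor is
f_L composed with f_F; the other paths exist only to debias it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from . import autodiff as ad
from .autodiff import Tensor, gather, segment_sum
from .mpnn import (
    GraphBatch,
    MPNNConfig,
    TrainConfig,
    head_output,
    init_readout_params,
    init_trunk_params,
    run_trunk,
    set2set_readout,
)

__all__ = [
    "CFRModel",
    "importance_weight",
    "ipm_wasserstein",
    "cfr_losses",
    "train_cfr",
    "predict",
]


# ------------------------------------------------------------ closed-form w_i
def importance_weight(phi, d: int) -> float:
    """w = 1 + exp(phi^(1-d) - phi^(d)) = 1 / softmax probability of class d.

    Computed in log-sum-exp form so extreme scores cannot overflow: the
    exponent is capped at 700 (beyond which float64 would saturate anyway).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (2,) or not np.isfinite(phi).all():
        raise ValueError("phi must be a finite 2-vector")
    if d not in (0, 1):
        raise ValueError("d must be 0 or 1")
    return 1.0 + float(np.exp(min(phi[1 - d] - phi[d], 700.0)))


def importance_weights(phi: np.ndarray, d: int = 1) -> np.ndarray:
    """Vectorized :func:`importance_weight` over rows of an (n x 2) array."""
    phi = np.asarray(phi, dtype=float)
    return 1.0 + np.exp(np.minimum(phi[:, 1 - d] - phi[:, d], 700.0))


# ----------------------------------------------------------------- transport
def _pairwise_dist(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    sq = (a * a).sum(axis=1, keepdims=True) + (b * b).sum(axis=1, keepdims=True).T - 2.0 * (a @ b.T)
    return ad.sqrt(ad.relu(sq) + eps)


def _sinkhorn_plan(C: np.ndarray, reg: float, n_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    """Entropic OT plan for uniform marginals, log-domain stabilized."""
    n, m = C.shape
    log_a, log_b = -np.log(n), -np.log(m)
    f = np.zeros(n)
    g = np.zeros(m)
    for _ in range(n_iter):
        M = (-C + f[:, None] + g[None, :]) / reg
        f_upd = f + reg * (log_a - _logsumexp(M, axis=1))
        M = (-C + f_upd[:, None] + g[None, :]) / reg
        g_upd = g + reg * (log_b - _logsumexp(M, axis=0))
        delta = max(np.abs(f_upd - f).max(), np.abs(g_upd - g).max())
        f, g = f_upd, g_upd
        if delta < tol:
            break
    return np.exp((-C + f[:, None] + g[None, :]) / reg)


def _logsumexp(M: np.ndarray, axis: int) -> np.ndarray:
    mx = M.max(axis=axis)
    return mx + np.log(np.exp(M - np.expand_dims(mx, axis)).sum(axis=axis))


def _exact_plan(C: np.ndarray) -> np.ndarray:
    """Exact OT plan for uniform marginals via linear programming."""
    n, m = C.shape
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP on a feasible polytope
        raise RuntimeError(f"exact OT solve failed: {res.message}")
    return res.x.reshape(n, m)


def ipm_wasserstein(z_train, z_test, method: str = "sinkhorn", reg: float = 0.05, n_iter: int = 200):
    """Wasserstein distance between two embedding point clouds.

    Uniform marginals, Euclidean ground cost. ``method='exact'`` solves
    the transport linear program (use in tests; returns a float).
    ``method='sinkhorn'`` uses entropic regularization; if the inputs are
    autodiff tensors the transport plan is treated as a constant and the
    gradient flows through the cost matrix (the envelope-theorem gradient
    of entropic OT with respect to the ground costs).
    """
    ta = z_train if isinstance(z_train, Tensor) else Tensor(np.atleast_2d(z_train))
    tb = z_test if isinstance(z_test, Tensor) else Tensor(np.atleast_2d(z_test))
    if ta.shape[0] == 0 or tb.shape[0] == 0:
        raise ValueError("both point clouds must be nonempty")
    dist = _pairwise_dist(ta, tb)
    if method == "exact":
        # exact ground distances, no regularization smoothing
        C = np.sqrt(
            np.maximum(
                (ta.data**2).sum(1)[:, None] + (tb.data**2).sum(1)[None, :] - 2 * ta.data @ tb.data.T,
                0.0,
            )
        )
        return float((_exact_plan(C) * C).sum())
    if method != "sinkhorn":
        raise ValueError(f"unknown OT method {method!r}")
    plan = _sinkhorn_plan(dist.data, reg=reg, n_iter=n_iter)
    cost = (Tensor(plan) * dist).sum()
    return cost if (ta.requires_grad or tb.requires_grad) else float(cost.data)


# -------------------------------------------------------------------- model
class CFRModel:
    """Shared trunk + label readout + weight readout (+ mean-pool IPM path)."""

    def __init__(self, config: MPNNConfig, atom_vocab, bond_vocab, seed: int = 0, alpha: float = 10.0):
        if alpha < 0:
            raise ValueError("alpha must be nonnegative")
        self.config = config
        self.atom_vocab = tuple(atom_vocab)
        self.bond_vocab = tuple(bond_vocab)
        self.alpha = float(alpha)
        rng = np.random.default_rng(seed)
        D = config.hidden_dim
        self.trunk = init_trunk_params(rng, len(self.atom_vocab), self.bond_vocab, D)
        self.label_head = init_readout_params(rng, D, 1, "label")
        self.weight_head = init_readout_params(rng, D, 2, "weight")
        self.y_mean = 0.0
        self.y_std = 1.0

    def batch(self, graphs) -> GraphBatch:
        return GraphBatch(graphs, self.atom_vocab, self.bond_vocab)

    # f_F: node states from the shared trunk
    def features(self, batch: GraphBatch) -> Tensor:
        return run_trunk(batch, self.trunk, self.config.n_layers)

    def graph_embeddings(self, h: Tensor, batch: GraphBatch) -> Tensor:
        counts = np.bincount(batch.node2graph, minlength=batch.n_graphs).reshape(-1, 1)
        return segment_sum(h, batch.node2graph, batch.n_graphs) * Tensor(1.0 / counts)

    def label_output(self, h: Tensor, batch: GraphBatch) -> Tensor:
        q = set2set_readout(h, batch, self.label_head, "label", self.config.set2set_steps)
        return head_output(q, self.label_head, "label")

    def weight_scores(self, h: Tensor, batch: GraphBatch) -> Tensor:
        q = set2set_readout(h, batch, self.weight_head, "weight", self.config.set2set_steps)
        return head_output(q, self.weight_head, "weight")

    def all_params(self) -> dict:
        return {**self.trunk, **self.label_head, **self.weight_head}

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.all_params().items()}

    def load_state_dict(self, state: dict):
        for k, p in self.all_params().items():
            p.data = state[k].copy()


@dataclass
class CFRBatch:
    graphs: list
    domains: np.ndarray  # 1 = biased training domain, 0 = test domain
    y: np.ndarray  # labels; meaningful only where domains == 1


def cfr_losses(batch: CFRBatch, model: CFRModel, ipm_method: str = "sinkhorn"):
    """(o_property, o_ipm, o_domain) for one mixed-domain mini-batch.

    o_property is the importance-weighted squared loss over labeled
    molecules; the weights come from the frozen weight head (no gradient
    flows into f_W through them, and d is fixed to 1). o_ipm is the
    Wasserstein distance between the domain-split graph embeddings.
    o_domain is the softmax cross-entropy of the weight head's scores.
    """
    d = np.asarray(batch.domains, dtype=int)
    labeled = np.flatnonzero(d == 1)
    if labeled.size == 0:
        raise ValueError("batch has no labeled (training-domain) molecules")
    gb = model.batch(batch.graphs)
    h = model.features(gb)

    # --- weights from the frozen f_W (constants in step A)
    phi_all = model.weight_scores(h, gb).data  # .data: detached by construction
    w = importance_weights(phi_all[labeled], d=1)

    pred = model.label_output(h, gb)
    resid = gather(pred, labeled) - Tensor(batch.y[labeled].reshape(-1, 1))
    o_property = (Tensor(w.reshape(-1, 1)) * resid * resid).mean()

    test_idx = np.flatnonzero(d == 0)
    if test_idx.size:
        z = model.graph_embeddings(h, gb)
        o_ipm = ipm_wasserstein(gather(z, labeled), gather(z, test_idx), method=ipm_method)
        if not isinstance(o_ipm, Tensor):
            o_ipm = Tensor(o_ipm)
    else:
        o_ipm = Tensor(0.0)

    # --- o_domain: recomputed through f_W so step B reaches its parameters,
    #     but on detached features so f_F receives no domain gradient
    phi = model.weight_scores(h.detach(), gb)
    mx = phi.data.max(axis=1, keepdims=True)
    lse = Tensor(mx) + ad.log(ad.exp(phi - Tensor(mx)).sum(axis=1, keepdims=True))
    picked = (phi * Tensor(np.eye(2)[d])).sum(axis=1, keepdims=True)
    o_domain = (lse - picked).mean()
    return o_property, o_ipm, o_domain


def train_cfr(
    train_graphs,
    y_train: np.ndarray,
    test_graphs,
    mpnn_cfg: MPNNConfig,
    train_cfg: TrainConfig,
    alpha: float = 10.0,
    atom_vocab=None,
    bond_vocab=None,
    ipm_method: str = "sinkhorn",
) -> tuple:
    """Alternating minimization: step A (f_F, f_L on o_property + alpha*o_ipm),
    step B (f_W on o_domain), one of each per mini-batch.

    Model selection: checkpoint with the lowest validation regression
    loss on a held-out 20% of the training set (plain MSE so checkpoints
    are comparable while f_W is still moving). Returns (model, history).
    """
    y_train = np.asarray(y_train, dtype=float)
    model = CFRModel(mpnn_cfg, atom_vocab, bond_vocab, seed=train_cfg.seed, alpha=alpha)
    rng = np.random.default_rng(train_cfg.seed)

    n_tr = len(train_graphs)
    n_val = max(1, int(round(train_cfg.val_fraction * n_tr))) if n_tr > 1 else 0
    perm = rng.permutation(n_tr)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(fit_idx) == 0:
        fit_idx = perm

    model.y_mean = float(np.mean(y_train[fit_idx]))
    model.y_std = float(np.std(y_train[fit_idx])) or 1.0
    y_scaled = (y_train - model.y_mean) / model.y_std

    fit_graphs = [train_graphs[i] for i in fit_idx]
    fit_y = y_scaled[fit_idx]
    test_graphs = list(test_graphs)
    val_batch = model.batch([train_graphs[i] for i in val_idx]) if n_val else None

    opt_main = ad.Adam({**model.trunk, **model.label_head}, lr=train_cfg.initial_lr)
    opt_w = ad.Adam(model.weight_head, lr=train_cfg.initial_lr)
    sched = ad.ReduceLROnPlateau(opt_main, factor=train_cfg.plateau_factor, patience=train_cfg.plateau_patience)
    history = {"train_loss": [], "val_loss": [], "domain_loss": [], "ipm": [], "lr": []}
    best_val, best_state = np.inf, model.state_dict()

    half = max(1, train_cfg.batch_size // 2)
    for epoch in range(train_cfg.max_epochs):
        tr_order = rng.permutation(len(fit_graphs))
        te_order = rng.permutation(len(test_graphs))
        n_steps = max(1, int(np.ceil(len(tr_order) / half)))
        ep_prop, ep_dom, ep_ipm = 0.0, 0.0, 0.0
        for step in range(n_steps):
            tr_idx = tr_order[step * half : (step + 1) * half]
            if tr_idx.size == 0:
                continue
            # cycle through the test pool so every batch carries both domains
            te_take = (np.arange(half) + step * half) % max(len(te_order), 1)
            te_idx = te_order[te_take] if len(test_graphs) else np.array([], dtype=int)
            graphs = [fit_graphs[i] for i in tr_idx] + [test_graphs[i] for i in te_idx]
            domains = np.array([1] * tr_idx.size + [0] * te_idx.size)
            yb = np.concatenate([fit_y[tr_idx], np.zeros(te_idx.size)])
            cb = CFRBatch(graphs=graphs, domains=domains, y=yb)

            o_prop, o_ipm, o_dom = cfr_losses(cb, model, ipm_method=ipm_method)
            total = o_prop + model.alpha * o_ipm
            if not np.isfinite(total.data):
                model.load_state_dict(best_state)
                raise FloatingPointError(f"non-finite CFR loss at epoch {epoch}")
            # step A: feature extractor + label path (f_W scores held constant)
            opt_main.zero_grad()
            opt_w.zero_grad()
            total.backward()
            opt_main.step()
            # step B: weight estimator alone
            opt_main.zero_grad()
            opt_w.zero_grad()
            o_dom.backward()
            opt_w.step()
            opt_w.lr = opt_main.lr  # schedulers move together
            ep_prop += float(o_prop.data)
            ep_dom += float(o_dom.data)
            ep_ipm += float(o_ipm.data)

        if val_batch is not None:
            hv = model.features(val_batch)
            vpred = model.label_output(hv, val_batch)
            vresid = vpred.data[:, 0] - y_scaled[val_idx]
            vloss = float(np.mean(vresid**2))
        else:
            vloss = ep_prop / n_steps
        history["train_loss"].append(ep_prop / n_steps)
        history["domain_loss"].append(ep_dom / n_steps)
        history["ipm"].append(ep_ipm / n_steps)
        history["val_loss"].append(vloss)
        history["lr"].append(opt_main.lr)
        if vloss < best_val:
            best_val = vloss
            best_state = model.state_dict()
        sched.step(vloss)
        if opt_main.lr < train_cfg.min_lr:
            break

    model.load_state_dict(best_state)
    return model, history


def predict(model: CFRModel, graphs) -> np.ndarray:
    """Deliverable predictor: f_L(f_F(G)), back on the target scale."""
    gb = model.batch(graphs)
    h = model.features(gb)
    out = model.label_output(h, gb).data[:, 0]
    return out * model.y_std + model.y_mean
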