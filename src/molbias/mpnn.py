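"""Message-passing neural network for molecular graphs.

Architecture: atom one-hots are linearly embedded to ``D`` dimensions;
``T`` rounds of bond-type-conditioned message passing follow, where node
``v`` receives ``m_v = ReLU(sum_{u in N(v)} W_{bond(v,u)} h_u)`` (each
undirected bond contributes in both directions, message weights shared
across rounds) and updates its state through a GRU cell with ``m_v`` as
input. The final node states are aggregated by a set2set readout — an
LSTM-driven attention recurrence that is invariant to node order — and
two linear layers map the readout to the head output: a scalar for
regression, a logistic probability for binary classification, or the
raw graph vector for feature extraction.

Training is mini-batch Adam with a reduce-on-plateau learning-rate
schedule monitored on a held-out validation split; the parameters with
the lowest validation loss seen are returned. Regression targets are
standardized internally (train mean/sd) and predictions mapped back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, gather, segment_sum
from .molgraph import MolecularGraph, encode_atoms

__all__ = [
    "MPNNConfig",
    "TrainConfig",
    "GraphBatch",
    "MPNN",
    "train",
    "weighted_mse",
    "binary_cross_entropy",
]


@dataclass
class MPNNConfig:
    n_layers: int = 3
    hidden_dim: int = 32
    set2set_steps: int = 3
    readout: str = "seq2seq_2linear"
    head: str = "regression"  # regression | binary_classification | feature_only

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if self.head not in ("regression", "binary_classification", "feature_only"):
            raise ValueError(f"unknown head {self.head!r}")


@dataclass
class TrainConfig:
    initial_lr: float = 1e-5
    plateau_factor: float = 0.7
    plateau_patience: int = 5
    batch_size: int = 64
    max_epochs: int = 200
    min_lr: float = 1e-7
    val_fraction: float = 0.2
    seed: int = 0


class GraphBatch:
    """A disjoint union of graphs packed for vectorized message passing.

    ``x``: stacked one-hot atom features (N_nodes x |vocab|);
    ``edges_by_type``: per bond type, (src, dst) index arrays containing
    both directions of every undirected bond; ``node2graph``: segment id
    of each node; ``n_graphs``: number of graphs in the batch.
    """

    def __init__(self, graphs, atom_vocab, bond_vocab):
        xs, seg = [], []
        srcs = {b: [] for b in bond_vocab}
        dsts = {b: [] for b in bond_vocab}
        offset = 0
        for gi, g in enumerate(graphs):
            xs.append(encode_atoms(g, atom_vocab))
            seg.extend([gi] * g.n_atoms)
            for u, v, b in g.edges:
                srcs[b].extend((offset + u, offset + v))
                dsts[b].extend((offset + v, offset + u))
            offset += g.n_atoms
        self.x = np.concatenate(xs, axis=0)
        self.node2graph = np.asarray(seg, dtype=np.intp)
        self.n_graphs = len(graphs)
        self.n_nodes = offset
        self.edges_by_type = {
            b: (np.asarray(srcs[b], dtype=np.intp), np.asarray(dsts[b], dtype=np.intp))
            for b in bond_vocab
            if srcs[b]
        }


# ------------------------------------------------------------------ the model
def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


def init_readout_params(rng, D: int, out_dim: int, prefix: str) -> dict:
    """Set2set LSTM + two linear layers mapping the 2D readout to out_dim."""
    return {
        f"{prefix}.lstm_W": Tensor(_glorot(rng, (2 * D, 4 * D)), requires_grad=True),
        f"{prefix}.lstm_U": Tensor(_glorot(rng, (D, 4 * D)), requires_grad=True),
        f"{prefix}.lstm_b": Tensor(np.zeros(4 * D), requires_grad=True),
        f"{prefix}.lin1_W": Tensor(_glorot(rng, (2 * D, D)), requires_grad=True),
        f"{prefix}.lin1_b": Tensor(np.zeros(D), requires_grad=True),
        f"{prefix}.lin2_W": Tensor(_glorot(rng, (D, out_dim)), requires_grad=True),
        f"{prefix}.lin2_b": Tensor(np.zeros(out_dim), requires_grad=True),
    }


def init_trunk_params(rng, vocab_size: int, bond_vocab, D: int) -> dict:
    params = {
        "embed_W": Tensor(_glorot(rng, (vocab_size, D)), requires_grad=True),
        "embed_b": Tensor(np.zeros(D), requires_grad=True),
    }
    for b in bond_vocab:
        params[f"msg_W.{b}"] = Tensor(_glorot(rng, (D, D)), requires_grad=True)
    for gate in ("z", "r", "n"):
        params[f"gru_W{gate}"] = Tensor(_glorot(rng, (D, D)), requires_grad=True)
        params[f"gru_U{gate}"] = Tensor(_glorot(rng, (D, D)), requires_grad=True)
        params[f"gru_b{gate}"] = Tensor(np.zeros(D), requires_grad=True)
    return params


def message_pass(h: Tensor, batch: GraphBatch, params: dict) -> Tensor:
    """m_v = ReLU(sum over neighbors of W_{bond} h_u), both bond directions."""
    total = None
    for b, (src, dst) in batch.edges_by_type.items():
        contrib = segment_sum(gather(h, src) @ params[f"msg_W.{b}"], dst, batch.n_nodes)
        total = contrib if total is None else total + contrib
    if total is None:  # edgeless batch: empty neighbor sums
        total = Tensor(np.zeros((batch.n_nodes, h.shape[1])))
    return ad.relu(total)


def gru_update(h: Tensor, m: Tensor, params: dict) -> Tensor:
    """Standard GRU cell: message as input, node state as hidden state."""
    z = ad.sigmoid(m @ params["gru_Wz"] + h @ params["gru_Uz"] + params["gru_bz"])
    r = ad.sigmoid(m @ params["gru_Wr"] + h @ params["gru_Ur"] + params["gru_br"])
    n = ad.tanh(m @ params["gru_Wn"] + (r * h) @ params["gru_Un"] + params["gru_bn"])
    return (1.0 - z) * n + z * h


def run_trunk(batch: GraphBatch, params: dict, n_layers: int) -> Tensor:
    """Embed atoms and apply ``n_layers`` rounds of message passing + GRU."""
    h = Tensor(batch.x) @ params["embed_W"] + params["embed_b"]
    for _ in range(n_layers):
        m = message_pass(h, batch, params)
        h = gru_update(h, m, params)
    return h


def set2set_readout(h: Tensor, batch: GraphBatch, params: dict, prefix: str, steps: int) -> Tensor:
    """Order-invariant attention readout; returns a (G x 2D) graph matrix."""
    G, D = batch.n_graphs, h.shape[1]
    q = Tensor(np.zeros((G, D)))
    c = Tensor(np.zeros((G, D)))
    q_star = Tensor(np.zeros((G, 2 * D)))
    seg = batch.node2graph
    for _ in range(steps):
        gates = q_star @ params[f"{prefix}.lstm_W"] + q @ params[f"{prefix}.lstm_U"] + params[f"{prefix}.lstm_b"]
        i_g = ad.sigmoid(gates[:, 0:D])
        f_g = ad.sigmoid(gates[:, D : 2 * D])
        g_g = ad.tanh(gates[:, 2 * D : 3 * D])
        o_g = ad.sigmoid(gates[:, 3 * D : 4 * D])
        c = f_g * c + i_g * g_g
        q = o_g * ad.tanh(c)
        # attention over nodes within each graph
        logits = (h * gather(q, seg)).sum(axis=1, keepdims=True)
        seg_max = np.full((G, 1), -np.inf)
        np.maximum.at(seg_max, seg, logits.data)  # detached max for stability
        e = ad.exp(logits - Tensor(seg_max[seg]))
        denom = segment_sum(e, seg, G)
        a = e / gather(denom, seg)
        r = segment_sum(a * h, seg, G)
        q_star = concat([q, r], axis=1)
    return q_star


def head_output(q_star: Tensor, params: dict, prefix: str) -> Tensor:
    hidden = ad.relu(q_star @ params[f"{prefix}.lin1_W"] + params[f"{prefix}.lin1_b"])
    return hidden @ params[f"{prefix}.lin2_W"] + params[f"{prefix}.lin2_b"]


class MPNN:
    """A message-passing network with a chosen head.

    ``forward`` returns the raw head output per graph (a (G x 1) tensor;
    logits for the classification head). ``predict`` returns a numpy
    vector on the target scale (probabilities for classification).
    """

    def __init__(self, config: MPNNConfig, atom_vocab, bond_vocab, seed: int = 0):
        self.config = config
        self.atom_vocab = tuple(atom_vocab)
        self.bond_vocab = tuple(bond_vocab)
        rng = np.random.default_rng(seed)
        D = config.hidden_dim
        self.params = init_trunk_params(rng, len(self.atom_vocab), self.bond_vocab, D)
        if config.head != "feature_only":
            self.params.update(init_readout_params(rng, D, 1, "head"))
        self.y_mean = 0.0
        self.y_std = 1.0

    # ----------------------------------------------------------------- passes
    def batch(self, graphs) -> GraphBatch:
        return GraphBatch(graphs, self.atom_vocab, self.bond_vocab)

    def node_states(self, batch: GraphBatch) -> Tensor:
        return run_trunk(batch, self.params, self.config.n_layers)

    def forward(self, batch: GraphBatch) -> Tensor:
        h = self.node_states(batch)
        if self.config.head == "feature_only":
            # graph-level features by mean pooling (no readout parameters)
            counts = np.bincount(batch.node2graph, minlength=batch.n_graphs).reshape(-1, 1)
            return segment_sum(h, batch.node2graph, batch.n_graphs) * Tensor(1.0 / counts)
        q_star = set2set_readout(h, batch, self.params, "head", self.config.set2set_steps)
        return head_output(q_star, self.params, "head")

    def predict(self, graphs) -> np.ndarray:
        out = self.forward(self.batch(graphs)).data[:, 0]
        if self.config.head == "regression":
            return out * self.y_std + self.y_mean
        if self.config.head == "binary_classification":
            return 1.0 / (1.0 + np.exp(-np.clip(out, -60, 60)))
        return out

    # ------------------------------------------------------------- state mgmt
    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, p in self.params.items():
            p.data = state[k].copy()


# ------------------------------------------------------------------- training
def weighted_mse(pred: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    resid = pred - Tensor(y.reshape(-1, 1))
    return (Tensor(weights.reshape(-1, 1)) * resid * resid).mean()


def binary_cross_entropy(logits: Tensor, labels: np.ndarray, weights: np.ndarray) -> Tensor:
    """Stable BCE with logits: relu(z) - z*y + log(1 + exp(-|z|))."""
    y = Tensor(labels.reshape(-1, 1))
    w = Tensor(weights.reshape(-1, 1))
    absz = ad.relu(logits) + ad.relu(-logits)
    loss = ad.relu(logits) - logits * y + ad.log(1.0 + ad.exp(-absz))
    return (w * loss).mean()


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def train(model: MPNN, graphs, y: np.ndarray, cfg: TrainConfig, weights: np.ndarray | None = None):
    """Fit ``model`` on (graphs, y) with per-instance loss weights.

    Returns ``(model, history)``; the model carries the parameters that
    achieved the lowest validation loss. All-ones weights give the plain
    unweighted objective. Aborts on a non-finite loss.
    """
    if len(graphs) == 0:
        raise ValueError("empty training data")
    y = np.asarray(y, dtype=float)
    if weights is None:
        weights = np.ones(len(graphs))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(graphs):
        raise ValueError("weights length mismatch")

    rng = np.random.default_rng(cfg.seed)
    n = len(graphs)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm

    if model.config.head == "regression":
        model.y_mean = float(np.mean(y[tr_idx]))
        model.y_std = float(np.std(y[tr_idx])) or 1.0
        y_scaled = (y - model.y_mean) / model.y_std
        loss_fn = weighted_mse
    else:
        y_scaled = y
        loss_fn = binary_cross_entropy

    tr_graphs = [graphs[i] for i in tr_idx]
    val_batch = model.batch([graphs[i] for i in val_idx]) if n_val else None

    opt = ad.Adam(model.params, lr=cfg.initial_lr)
    sched = ad.ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience, min_lr=0.0)
    hist = TrainHistory()
    best_state = model.state_dict()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(tr_graphs))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = model.batch([tr_graphs[i] for i in idx])
            pred = model.forward(batch)
            loss = loss_fn(pred, y_scaled[tr_idx][idx], weights[tr_idx][idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr={opt.lr:.2e})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data)
            n_batches += 1
        ep_loss /= max(n_batches, 1)

        if val_batch is not None:
            vpred = model.forward(val_batch)
            vloss = float(loss_fn(vpred, y_scaled[val_idx], weights[val_idx]).data)
        else:
            vloss = ep_loss
        hist.train_loss.append(ep_loss)
        hist.val_loss.append(vloss)
        hist.lr.append(opt.lr)
        if vloss < hist.best_val_loss:
            hist.best_val_loss = vloss
            hist.best_epoch = epoch
            best_state = model.state_dict()
        sched.step(vloss)
        if opt.lr < cfg.min_lr:
            break

    model.load_state_dict(best_state)
    return model, hist
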