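"""Inverse-propensity-scoring bias correction (two-step).

Step 1 fits a propensity model: a message-passing classifier trained to
separate the biased training molecules (label 1) from the unbiased test
molecules (label 0) using cross-entropy loss — target property values
are never seen by this step. The predicted probability of membership in
the biased set, clipped away from zero, is the estimated propensity
pi_hat(G).

Step 2 fits the property regressor with each molecule's squared loss
weighted by 1 / pi_hat(G). With correct propensities the weighted
empirical loss is unbiased for the loss under uniform sampling from the
chemical space, so minimizing it counteracts the selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mpnn import MPNN, MPNNConfig, TrainConfig, train

__all__ = ["PropensityScores", "fit_propensity", "ips_objective", "fit_ips_regressor"]


@dataclass
class PropensityScores:
    scores: dict  # molecule id -> pi_hat in [floor, 1]
    accuracy: float  # held-out domain-classification accuracy
    degenerate: bool  # True if the classifier output was (near) constant
    model: MPNN | None = None

    def vector(self, ids) -> np.ndarray:
        return np.array([self.scores[i] for i in ids], dtype=float)


def fit_propensity(
    train_graphs,
    test_graphs,
    mpnn_cfg: MPNNConfig,
    train_cfg: TrainConfig,
    atom_vocab,
    bond_vocab,
    floor: float = 0.01,
) -> PropensityScores:
    """Estimate pi_hat for every biased-training molecule.

    The validation split contains 20% of each set (stratified), and the
    checkpoint with the lowest validation cross-entropy scores the
    training molecules. A near-constant classifier is flagged as
    degenerate rather than raised.
    """
    if not train_graphs or not test_graphs:
        raise ValueError("both molecule sets must be nonempty")
    if mpnn_cfg.head != "binary_classification":
        raise ValueError("propensity model requires the binary_classification head")

    graphs = list(train_graphs) + list(test_graphs)
    labels = np.array([1.0] * len(train_graphs) + [0.0] * len(test_graphs))
    model = MPNN(mpnn_cfg, atom_vocab, bond_vocab, seed=train_cfg.seed)
    model, hist = train(model, graphs, labels, train_cfg)

    # held-out accuracy on the same stratification the trainer used
    rng = np.random.default_rng(train_cfg.seed)
    n = len(graphs)
    n_val = max(1, int(round(train_cfg.val_fraction * n)))
    val_idx = rng.permutation(n)[:n_val]
    val_probs = model.predict([graphs[i] for i in val_idx])
    accuracy = float(np.mean((val_probs > 0.5) == (labels[val_idx] > 0.5)))

    probs = model.predict(list(train_graphs))
    degenerate = bool(np.ptp(model.predict(graphs)) < 1e-6)
    scores = {g.id: float(np.clip(p, floor, 1.0)) for g, p in zip(train_graphs, probs)}
    return PropensityScores(scores=scores, accuracy=accuracy, degenerate=degenerate, model=model)


def ips_objective(y: np.ndarray, y_hat: np.ndarray, pi_hat: np.ndarray) -> float:
    """Inverse-propensity-weighted squared loss:
    ``(1/N) * sum_i (y_i - y_hat_i)^2 / pi_hat_i``."""
    y, y_hat, pi_hat = (np.asarray(a, dtype=float) for a in (y, y_hat, pi_hat))
    if not (len(y) == len(y_hat) == len(pi_hat)):
        raise ValueError("length mismatch")
    if (pi_hat <= 0).any():
        raise ValueError("propensity scores must be positive")
    return float(np.mean((y - y_hat) ** 2 / pi_hat))


def fit_ips_regressor(
    train_graphs,
    y: np.ndarray,
    scores: PropensityScores,
    mpnn_cfg: MPNNConfig,
    train_cfg: TrainConfig,
    atom_vocab,
    bond_vocab,
):
    """Weighted regression with weights 1 / pi_hat (delegates to mpnn.train)."""
    if mpnn_cfg.head != "regression":
        raise ValueError("property model requires the regression head")
    weights = 1.0 / scores.vector([g.id for g in train_graphs])
    model = MPNN(mpnn_cfg, atom_vocab, bond_vocab, seed=train_cfg.seed)
    return train(model, list(train_graphs), y, train_cfg, weights=weights)
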