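"""Biased-sampling scenarios: indicators, sigmoid inclusion, gain tuning.

Four selection scenarios mimic how experimental datasets over-represent
parts of chemical space:

1. fewer atoms preferred (small molecules are better explored),
2. fewer single bonds preferred (stronger spectral manifestation),
3. higher auxiliary "gap"-like values preferred (more stable compounds),
4. higher target values preferred (researchers chase strong effects).

Each molecule's inclusion chance is a sigmoid of its min-max-normalized
indicator; the sigmoid gain is tuned by bisection so that the average
inclusion probability over the candidate pool equals the configured rate
(10% by default). A trial first removes a uniformly random 10% test set,
then draws the biased training set from the remainder by one independent
Bernoulli inclusion flip per molecule — sampling without replacement, so
no molecule can appear in both sets.

The sigmoid offset ("pivot") is the empirical quantile of the normalized
indicator at level ``target_rate / 2`` toward the preferred end, which
makes the mean inclusion probability decrease continuously from 0.5
(gain -> 0) to below the target rate (gain -> infinity), so the tuned
gain always exists when the rate is achievable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molgraph import Dataset, MolecularGraph, PropertyTable

__all__ = [
    "ScenarioConfig",
    "TrialSplit",
    "indicator_value",
    "indicator_vector",
    "inclusion_probabilities",
    "tune_gain",
    "make_trial",
    "run_trials",
]

# scenario -> (indicator kind, direction)
_SCENARIO_TABLE = {
    1: ("n_atoms", "smaller_preferred"),
    2: ("frac_nonsingle", "larger_preferred"),
    3: ("aux_property", "larger_preferred"),
    4: ("target_property", "larger_preferred"),
}


@dataclass
class ScenarioConfig:
    scenario: int = 1
    target_property: str = "target_size_linked"
    aux_property: str | None = "gap_like"
    target_rate: float = 0.10
    test_fraction: float = 0.10
    n_trials: int = 30

    def __post_init__(self):
        if self.scenario not in _SCENARIO_TABLE:
            raise ValueError(f"unknown scenario {self.scenario}; must be 1-4")
        if not 0.0 < self.target_rate < 0.5:
            raise ValueError("target_rate must be in (0, 0.5)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.scenario == 3 and not self.aux_property:
            raise ValueError("scenario 3 requires an auxiliary property column")

    @property
    def indicator(self) -> str:
        return _SCENARIO_TABLE[self.scenario][0]

    @property
    def direction(self) -> str:
        return _SCENARIO_TABLE[self.scenario][1]


@dataclass
class TrialSplit:
    """One biased train set + unbiased test set (domain label d=1 for train)."""

    train_ids: list
    test_ids: list
    inclusion_probs: dict
    gain: float
    pivot: float
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")

    def domain_labels(self) -> np.ndarray:
        return np.array([1] * len(self.train_ids) + [0] * len(self.test_ids), dtype=int)


# ------------------------------------------------------------------ indicator
def indicator_value(g: MolecularGraph, props: PropertyTable, cfg: ScenarioConfig) -> float:
    kind = cfg.indicator
    if kind == "n_atoms":
        return float(g.n_atoms)
    if kind == "frac_nonsingle":
        if g.n_bonds == 0:
            return 0.0  # zero-bond convention: treat as all-single
        return sum(1 for _, _, b in g.edges if b != "single") / g.n_bonds
    if kind == "aux_property":
        return props.get(g.id, cfg.aux_property)
    if kind == "target_property":
        return props.get(g.id, cfg.target_property)
    raise ValueError(f"unknown indicator {kind!r}")


def indicator_vector(ds: Dataset, ids, cfg: ScenarioConfig) -> np.ndarray:
    return np.array([indicator_value(ds.graph(i), ds.properties, cfg) for i in ids], dtype=float)


# ------------------------------------------------------------------- sigmoid
def _normalize(xs: np.ndarray) -> np.ndarray:
    xs = np.asarray(xs, dtype=float)
    lo, hi = xs.min(), xs.max()
    if hi == lo:
        raise ValueError("constant indicator vector: min-max normalization undefined")
    return (xs - lo) / (hi - lo)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def _pivot(xn: np.ndarray, cfg: ScenarioConfig) -> float:
    level = cfg.target_rate / 2.0
    if cfg.direction == "smaller_preferred":
        return float(np.quantile(xn, level))
    return float(np.quantile(xn, 1.0 - level))


def inclusion_probabilities(xs: np.ndarray, gain: float, cfg: ScenarioConfig, pivot: float | None = None) -> np.ndarray:
    """Sigmoid inclusion chances over the candidate pool.

    Strictly decreasing in the normalized indicator for
    ``smaller_preferred`` and strictly increasing for
    ``larger_preferred``; equals 0.5 everywhere as ``gain -> 0``.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    xn = _normalize(xs)
    if pivot is None:
        pivot = _pivot(xn, cfg)
    if cfg.direction == "smaller_preferred":
        return _sigmoid(gain * (pivot - xn))
    return _sigmoid(gain * (xn - pivot))


def tune_gain(xs: np.ndarray, cfg: ScenarioConfig, tol: float = 1e-5) -> tuple:
    """Bisection for the gain bringing mean inclusion probability to the rate.

    Returns ``(gain, pivot)``. Raises if the target rate is outside the
    achievable range ``(limit at infinite gain, 0.5)``.
    """
    xn = _normalize(xs)
    pivot = _pivot(xn, cfg)

    def mean_p(gain: float) -> float:
        return float(inclusion_probabilities(xs, gain, cfg, pivot=pivot).mean())

    lo, hi = 1e-6, 1e6
    f_lo, f_hi = mean_p(lo), mean_p(hi)
    target = cfg.target_rate
    if not (f_hi <= target <= f_lo):
        raise ValueError(
            f"target rate {target} not achievable: mean inclusion probability "
            f"ranges over [{f_hi:.6f}, {f_lo:.6f}] for gain in [{lo}, {hi}]"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space; gain spans 12 decades
        if mean_p(mid) > target:
            lo = mid
        else:
            hi = mid
        if abs(mean_p(mid) - target) < tol:
            return float(mid), pivot
    raise RuntimeError("gain bisection did not converge")


# --------------------------------------------------------------------- trials
def make_trial(ds: Dataset, cfg: ScenarioConfig, seed: int) -> TrialSplit:
    """One biased train / unbiased test split, fully determined by ``seed``."""
    rng = np.random.default_rng(seed)
    ids = np.array(ds.ids())
    n_test = int(round(cfg.test_fraction * len(ids)))
    test_idx = rng.choice(len(ids), size=n_test, replace=False)
    test_mask = np.zeros(len(ids), dtype=bool)
    test_mask[test_idx] = True
    test_ids = list(ids[test_mask])
    pool_ids = list(ids[~test_mask])

    xs = indicator_vector(ds, pool_ids, cfg)
    gain, pivot = tune_gain(xs, cfg)
    probs = inclusion_probabilities(xs, gain, cfg, pivot=pivot)
    draws = rng.random(len(pool_ids))
    train_ids = [i for i, p, u in zip(pool_ids, probs, draws) if u < p]
    if not train_ids:
        raise RuntimeError(f"biased sampling drew an empty training set (seed={seed})")
    return TrialSplit(
        train_ids=train_ids,
        test_ids=test_ids,
        inclusion_probs={i: float(p) for i, p in zip(pool_ids, probs)},
        gain=gain,
        pivot=pivot,
        seed=seed,
    )


def run_trials(ds: Dataset, cfg: ScenarioConfig, base_seed: int = 0) -> list:
    """Repeat the sampling procedure ``cfg.n_trials`` times (seeds base+i)."""
    return [make_trial(ds, cfg, seed=base_seed + k) for k in range(cfg.n_trials)]
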