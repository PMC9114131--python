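"""End-to-end scenario orchestration.

One :class:`ExperimentConfig` drives the whole protocol: build the
dataset, draw ``n_trials`` biased train / unbiased test splits, train
each requested method (baseline / IPS / CFR) per trial, score test MAE,
and aggregate into an :class:`~molbias.evaluation.EvalReport` with
paired significance tests against the baseline. Every random draw is
traceable to ``base_seed``; trial results are checkpointed to disk so a
long run can resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import cfr as cfr_mod
from . import ips as ips_mod
from .evaluation import EvalReport, binned_mae, density_summary, mae
from .molgraph import Dataset, read_jsonl
from .mpnn import MPNN, MPNNConfig, TrainConfig, train
from .sampling import ScenarioConfig, TrialSplit, indicator_vector, make_trial
from .synthetic import default_benchmark

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "validate_report", "smoke_config"]


@dataclass
class ExperimentConfig:
    dataset: str = "default_benchmark"  # fixture name or path to a JSON-lines file
    dataset_size: int = 3000
    target_property: str = "target_size_linked"
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    methods: tuple = ("baseline", "ips", "cfr")
    mpnn: MPNNConfig = field(default_factory=MPNNConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    alpha: float = 10.0
    propensity_floor: float = 0.01
    n_trials: int = 30
    base_seed: int = 0
    n_bins: int = 10
    output_dir: str | None = None

    def __post_init__(self):
        if not self.methods:
            raise ValueError("at least one method required")
        unknown = set(self.methods) - {"baseline", "ips", "cfr"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if ("ips" in self.methods or "cfr" in self.methods) and "baseline" not in self.methods:
            raise ValueError("significance testing against the baseline requires the baseline method")

    def canonical(self) -> dict:
        d = asdict(self)
        d.pop("output_dir")
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.canonical(), sort_keys=True).encode()).hexdigest()[:16]


def _load_dataset(cfg: ExperimentConfig) -> Dataset:
    if cfg.dataset == "default_benchmark":
        return default_benchmark(seed=cfg.base_seed, n_molecules=cfg.dataset_size)
    return read_jsonl(cfg.dataset)


def _make_cfg(base: MPNNConfig, head: str) -> MPNNConfig:
    return MPNNConfig(
        n_layers=base.n_layers,
        hidden_dim=base.hidden_dim,
        set2set_steps=base.set2set_steps,
        readout=base.readout,
        head=head,
    )


def _train_cfg_for_trial(cfg: ExperimentConfig, seed: int) -> TrainConfig:
    t = cfg.training
    return TrainConfig(
        initial_lr=t.initial_lr,
        plateau_factor=t.plateau_factor,
        plateau_patience=t.plateau_patience,
        batch_size=t.batch_size,
        max_epochs=t.max_epochs,
        min_lr=t.min_lr,
        val_fraction=t.val_fraction,
        seed=seed,
    )


def _run_single_trial(ds: Dataset, cfg: ExperimentConfig, trial: int) -> dict:
    seed = cfg.base_seed + trial
    split = make_trial(ds, cfg.scenario, seed=seed)
    train_graphs = [ds.graph(i) for i in split.train_ids]
    test_graphs = [ds.graph(i) for i in split.test_ids]
    y_train = ds.properties.column(cfg.target_property, split.train_ids)
    y_test = ds.properties.column(cfg.target_property, split.test_ids)
    test_ind = indicator_vector(ds, split.test_ids, cfg.scenario)
    train_ind = indicator_vector(ds, split.train_ids, cfg.scenario)
    tcfg = _train_cfg_for_trial(cfg, seed)

    result = {
        "trial": trial,
        "seed": seed,
        "n_train": len(train_graphs),
        "n_test": len(test_graphs),
        "gain": split.gain,
        "train_indicators": train_ind.tolist(),
        "test_indicators": test_ind.tolist(),
        "mae": {},
        "binned": {},
    }

    predictions = {}
    if "baseline" in cfg.methods:
        model = MPNN(_make_cfg(cfg.mpnn, "regression"), ds.atom_vocab, ds.bond_vocab, seed=seed)
        model, _ = train(model, train_graphs, y_train, tcfg)
        predictions["baseline"] = model.predict(test_graphs)

    if "ips" in cfg.methods:
        scores = ips_mod.fit_propensity(
            train_graphs,
            test_graphs,
            _make_cfg(cfg.mpnn, "binary_classification"),
            tcfg,
            ds.atom_vocab,
            ds.bond_vocab,
            floor=cfg.propensity_floor,
        )
        result["propensity_accuracy"] = scores.accuracy
        model, _ = ips_mod.fit_ips_regressor(
            train_graphs, y_train, scores, _make_cfg(cfg.mpnn, "regression"), tcfg, ds.atom_vocab, ds.bond_vocab
        )
        predictions["ips"] = model.predict(test_graphs)

    if "cfr" in cfg.methods:
        model, _ = cfr_mod.train_cfr(
            train_graphs,
            y_train,
            test_graphs,
            _make_cfg(cfg.mpnn, "regression"),
            tcfg,
            alpha=cfg.alpha,
            atom_vocab=ds.atom_vocab,
            bond_vocab=ds.bond_vocab,
        )
        predictions["cfr"] = cfr_mod.predict(model, test_graphs)

    for method, pred in predictions.items():
        result["mae"][method] = mae(y_test, pred)
        result["binned"][method] = binned_mae(y_test, pred, test_ind, n_bins=cfg.n_bins).to_dict("records")
    return result


def run_experiment(cfg: ExperimentConfig) -> EvalReport:
    """Run all trials of a scenario and aggregate into an EvalReport.

    If ``cfg.output_dir`` is set, each trial's results are checkpointed
    as ``trial_<k>.json`` (reused on rerun when the config hash matches)
    and the final report is written as ``report.json``.
    """
    ds = _load_dataset(cfg)
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    chash = cfg.hash()

    trials = []
    failures = []
    for k in range(cfg.n_trials):
        ckpt = out / f"trial_{k}.json" if out else None
        if ckpt and ckpt.exists():
            cached = json.loads(ckpt.read_text())
            if cached.get("config_hash") == chash:
                trials.append(cached["result"])
                continue
        try:
            result = _run_single_trial(ds, cfg, k)
        except Exception as err:  # record and surface, do not halt the run
            logger.exception("trial %d failed", k)
            failures.append({"trial": k, "error": str(err)})
            continue
        trials.append(result)
        if ckpt:
            ckpt.write_text(json.dumps({"config_hash": chash, "result": result}, sort_keys=True))

    if not trials:
        raise RuntimeError(f"all {cfg.n_trials} trials failed: {failures}")

    per_trial = {m: [t["mae"][m] for t in trials] for m in cfg.methods}
    report = EvalReport.from_trials(cfg.target_property, cfg.scenario.scenario, per_trial)
    report.densities = {
        "indicator": density_summary(
            [t["train_indicators"] for t in trials],
            [t["test_indicators"] for t in trials],
            n_bins=cfg.n_bins,
        )
    }
    report.binned = {m: [t["binned"][m] for t in trials] for m in cfg.methods}
    report.propensity_accuracy = [t["propensity_accuracy"] for t in trials if "propensity_accuracy" in t]

    payload = {"config_hash": chash, "methods": list(cfg.methods), **report.to_dict()}
    if failures:
        payload["failures"] = failures
        payload["partial"] = True
    validate_report(payload)
    if out:
        (out / "report.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
    report.payload = payload
    return report


def smoke_config(**overrides) -> ExperimentConfig:
    """A desk-scale configuration: small network, short schedule, minutes on one CPU."""
    defaults = dict(
        dataset_size=3000,
        scenario=ScenarioConfig(scenario=1, n_trials=10),
        mpnn=MPNNConfig(n_layers=2, hidden_dim=16, set2set_steps=2),
        training=TrainConfig(initial_lr=5e-3, max_epochs=100, min_lr=3e-6, batch_size=64),
        n_trials=10,
        # balance weight sized so alpha * IPM is ~10-20% of the initial
        # property loss at this embedding scale (see docs/methods.md)
        alpha=0.1,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


# ----------------------------------------------------------- schema validation
def _check(instance, schema, path="$", errors=None):
    errors = [] if errors is None else errors
    stype = schema.get("type")
    if stype == "object":
        if not isinstance(instance, dict):
            errors.append(f"{path}: expected object")
            return errors
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{path}: missing required key {req!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, value in instance.items():
            if key in props:
                _check(value, props[key], f"{path}.{key}", errors)
            elif isinstance(extra, dict):
                _check(value, extra, f"{path}.{key}", errors)
    elif stype == "array":
        if not isinstance(instance, list):
            errors.append(f"{path}: expected array")
            return errors
        items = schema.get("items")
        if items:
            for i, v in enumerate(instance):
                _check(v, items, f"{path}[{i}]", errors)
    elif stype == "number":
        if not isinstance(instance, (int, float)) or isinstance(instance, bool):
            errors.append(f"{path}: expected number")
    elif stype == "integer":
        if not isinstance(instance, int) or isinstance(instance, bool):
            errors.append(f"{path}: expected integer")
    elif stype == "string":
        if not isinstance(instance, str):
            errors.append(f"{path}: expected string")
        elif "enum" in schema and instance not in schema["enum"]:
            errors.append(f"{path}: {instance!r} not in {schema['enum']}")
    return errors


def validate_report(payload: dict):
    """Validate a report dict against the shipped JSON schema; raise on errors."""
    schema = json.loads(resources.files("molbias").joinpath("schemas/report.schema.json").read_text())
    errors = _check(payload, schema)
    if errors:
        raise ValueError("report schema violations: " + "; ".join(errors))
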