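"""Evaluation: MAE, cross-trial aggregation, paired testing, diagnostics.

Accuracy is mean absolute error on the unbiased test set. Methods are
compared with the baseline by a paired t-test over per-trial MAEs
(pairing by trial seed): ``**`` marks p < 0.01 and ``*`` marks p < 0.05.
Two diagnostics localize where debiasing acts: MAE binned by the
scenario's selection indicator, and normalized train/test indicator
histograms averaged over trials (the density-shift view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mae", "stars_for_p", "paired_test", "binned_mae", "density_summary", "EvalReport"]


def mae(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute error ``(1/M) * sum |y_hat - y|``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.shape != y_hat.shape:
        raise ValueError("inputs must be nonempty and of equal length")
    return float(np.mean(np.abs(y_hat - y)))


def stars_for_p(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def paired_test(baseline_maes, method_maes) -> tuple:
    """Two-sided paired t-test on per-trial MAE differences -> (t, p, stars)."""
    a = np.asarray(baseline_maes, dtype=float)
    b = np.asarray(method_maes, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired trials")
    if np.allclose(a, b):
        return 0.0, 1.0, ""
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), stars_for_p(float(p))


def binned_mae(y, y_hat, indicators, n_bins: int = 10) -> pd.DataFrame:
    """Per-bin MAE over equal-width indicator bins.

    Columns: bin_left, bin_right, count, mae (NaN for empty bins). The
    count-weighted recombination of bin MAEs equals the global MAE.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ind = np.asarray(indicators, dtype=float)
    edges = np.linspace(ind.min(), ind.max(), n_bins + 1)
    which = np.clip(np.digitize(ind, edges[1:-1]), 0, n_bins - 1)
    rows = []
    abs_err = np.abs(y_hat - y)
    for b in range(n_bins):
        mask = which == b
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "count": int(mask.sum()),
                "mae": float(abs_err[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def density_summary(train_indicators, test_indicators, n_bins: int = 10) -> dict:
    """Average normalized histograms of train vs test indicators.

    Accepts either one array per side or a list of per-trial arrays; a
    common equal-width grid spans both sides, each per-trial histogram
    is normalized to sum to 1 over bins, then averaged across trials.
    """
    def _as_trials(x):
        if len(x) and np.isscalar(x[0]):
            return [np.asarray(x, dtype=float)]
        return [np.asarray(t, dtype=float) for t in x]

    tr = _as_trials(train_indicators)
    te = _as_trials(test_indicators)
    allv = np.concatenate(tr + te)
    edges = np.linspace(allv.min(), allv.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        edges = np.linspace(edges[0] - 0.5, edges[0] + 0.5, n_bins + 1)

    def _avg(trials):
        hists = []
        for t in trials:
            h, _ = np.histogram(t, bins=edges)
            total = h.sum()
            hists.append(h / total if total else h.astype(float))
        return np.mean(hists, axis=0)

    return {"edges": edges, "train": _avg(tr), "test": _avg(te)}


@dataclass
class EvalReport:
    """Cross-trial evaluation of one scenario run."""

    target: str
    scenario: int
    per_trial_mae: dict = field(default_factory=dict)  # method -> [mae per trial]
    summary: dict = field(default_factory=dict)  # method -> {mean, std, t, p, stars}
    binned: dict = field(default_factory=dict)  # method -> binned-MAE records
    densities: dict = field(default_factory=dict)
    propensity_accuracy: list = field(default_factory=list)

    @classmethod
    def from_trials(cls, target: str, scenario: int, per_trial_mae: dict, baseline: str = "baseline") -> "EvalReport":
        rep = cls(target=target, scenario=scenario, per_trial_mae={k: list(map(float, v)) for k, v in per_trial_mae.items()})
        n_trials = {len(v) for v in per_trial_mae.values()}
        if len(n_trials) > 1:
            raise ValueError("methods have inconsistent trial counts")
        for method, maes in per_trial_mae.items():
            entry = {"mean": float(np.mean(maes)), "std": float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0}
            if method != baseline and baseline in per_trial_mae and len(maes) >= 2:
                t, p, s = paired_test(per_trial_mae[baseline], maes)
                entry.update({"t": t, "p": p, "stars": s})
            rep.summary[method] = entry
        return rep

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "scenario": self.scenario,
            "per_trial_mae": self.per_trial_mae,
            "summary": self.summary,
            "binned": self.binned,
            "densities": {
                k: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv) for kk, vv in v.items()}
                for k, v in self.densities.items()
            },
            "propensity_accuracy": self.propensity_accuracy,
        }


def plot_report(report: EvalReport, path):  # pragma: no cover - optional plotting
    """Bar chart of mean MAE per method with significance stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(report.summary)
    means = [report.summary[m]["mean"] for m in methods]
    stds = [report.summary[m]["std"] for m in methods]
    fig, ax = plt.subplots(figsize=(4, 3))
    bars = ax.bar(methods, means, yerr=stds, capsize=3)
    for m, bar in zip(methods, bars):
        s = report.summary[m].get("stars", "")
        if s:
            ax.text(bar.get_x() + bar.get_width() / 2, bar.get_height(), s, ha="center", va="bottom")
    ax.set_ylabel("test MAE")
    ax.set_title(f"{report.target} / scenario {report.scenario}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
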