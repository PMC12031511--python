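"""Metrics, bootstrap reporting, and method comparison.

Classification performance is summarized by AUROC and AUPRC (average
precision — the tie-robust, non-interpolated formulation), with AUPRC the
headline metric for the imbalanced mortality outcome.  Regression uses
MSE/RMSE/MAE over records.  Uncertainty is reported as mean ± std over B
bootstrap resamples of the test set (sample std, ddof=1); method
comparisons use a t-test on the replicate vectors, paired over shared
resample indices when both methods were bootstrapped with the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .heads import mae_loss, mse_loss, rmse_loss

CLASSIFICATION_METRICS = ("auprc", "auroc")
REGRESSION_METRICS = ("mse", "rmse", "mae")


class UndefinedMetricError(ValueError):
    pass


def auroc(scores, labels) -> float:
    """Probability a positive outranks a negative (ties count half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))

def auprc(scores, labels) -> float:
    """Average precision: sum of precision-at-rank over the positives."""
    labels = np.asarray(labels)
    if not (labels == 1).any():
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


_METRIC_FNS = {"auprc": auprc, "auroc": auroc,
               "mse": mse_loss, "rmse": rmse_loss, "mae": mae_loss}


@dataclass
class MetricSummary:
    point: float
    replicates: list[float]
    mean: float
    std: float


@dataclass
class EvalReport:
    task: str
    n: int
    B: int
    seed: int
    metrics: dict[str, MetricSummary] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "task": self.task, "n": self.n, "B": self.B, "seed": self.seed,
            "metrics": {k: {"point": m.point, "replicates": m.replicates,
                            "mean": m.mean, "std": m.std}
                        for k, m in self.metrics.items()},
            "comparisons": self.comparisons,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_row(self) -> dict[str, str]:
        """Formatted "mean ± std" strings; classification metrics ×100."""
        out = {}
        for k, m in self.metrics.items():
            scale = 100.0 if k in CLASSIFICATION_METRICS else 1.0
            out[k] = f"{m.mean * scale:.2f} ± {m.std * scale:.2f}"
        return out


def bootstrap_report(predictions, targets, task: str, B: int = 10,
                     seed: int = 0, max_redraws: int = 1000) -> EvalReport:
    """Bootstrap the test set B times and summarize every task metric.

    Each replicate resamples n test items with replacement.  For
    classification, a resample containing a single class leaves AUROC/AUPRC
    undefined and is redrawn.  With B=1 the std is reported as 0.0 (with a
    warning) since a single replicate carries no spread information.
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = len(targets)
    if n == 0 or len(predictions) != n:
        raise ValueError("bootstrap_report: empty or mismatched inputs")
    names = CLASSIFICATION_METRICS if task == "classification" \
        else REGRESSION_METRICS
    if B < 2:
        import warnings
        warnings.warn("B=1 bootstrap: std reported as 0", stacklevel=2)
    rng = np.random.default_rng(seed)
    replicate_idx = []
    for _ in range(B):
        for _try in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if task != "classification" or len(np.unique(targets[idx])) > 1:
                break
        else:
            raise UndefinedMetricError(
                "could not draw a two-class bootstrap resample")
        replicate_idx.append(idx)

    report = EvalReport(task=task, n=n, B=B, seed=seed)
    for name in names:
        fn = _METRIC_FNS[name]
        if task == "classification":
            point = fn(predictions, targets)
            reps = [fn(predictions[idx], targets[idx]) for idx in replicate_idx]
        else:
            point = fn(predictions, targets)
            reps = [fn(predictions[idx], targets[idx]) for idx in replicate_idx]
        arr = np.asarray(reps)
        report.metrics[name] = MetricSummary(
            point=point, replicates=[float(r) for r in reps],
            mean=float(arr.mean()),
            std=float(arr.std(ddof=1)) if B > 1 else 0.0)
    return report


def compare_methods(replicates_a, replicates_b,
                    paired: bool = True) -> tuple[float, str]:
    """Two-sided t-test between two methods' bootstrap replicate vectors.

    Paired mode requires equal replicate counts (same resample indices);
    unpaired mode uses Welch's correction.  Returns (p_value, direction)
    where direction is "A>B", "B>A" or "equal" by mean difference.  Two
    identical zero-variance vectors give p = 1.0 by convention.
    """
    a = np.asarray(replicates_a, dtype=float)
    b = np.asarray(replicates_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal replicate counts")
    mean_diff = a.mean() - b.mean()
    direction = "A>B" if mean_diff > 0 else ("B>A" if mean_diff < 0 else "equal")
    if a.std() == 0.0 and b.std() == 0.0:
        return (1.0 if mean_diff == 0 else 0.0), direction
    if paired:
        if np.std(a - b) == 0.0:
            return (1.0 if mean_diff == 0 else 0.0), direction
        t = stats.ttest_rel(a, b)
    else:
        t = stats.ttest_ind(a, b, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):
        p = 1.0
    return p, direction


def summary_table(reports: dict[str, EvalReport]) -> "object":
    """Method × metric table of formatted strings (a pandas DataFrame)."""
    import pandas as pd
    return pd.DataFrame({name: rep.summary_row()
                         for name, rep in reports.items()}).T
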