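"""Model evaluation statistics, implemented exactly as the study prints them.

Two conventions here deliberately deviate from the textbook forms and are
kept because they are the quantities the study reports:

* ``r_squared`` is the ratio-of-sums form sum((xhat_i - xbar)^2) /
  sum((x_i - xbar)^2) with xbar the mean of the *actual* values — not
  1 - SSres/SStot.  It equals the conventional R^2 only in special cases
  (e.g. least-squares-fitted predictions); in general it measures how much
  spread around the true mean the predictions reproduce.
* ``rmse`` divides by n - 1, not n.
* boxplot whiskers sit at 1 x IQR beyond the quartiles (not the usual 1.5x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BoxplotStats",
    "EvalReport",
    "UndefinedMetricError",
    "boxplot_stats",
    "evaluate_model",
    "r_squared",
    "rmse",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. constant actual values)."""


def _pair(predicted, actual):
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 paired values")
    return p, a


def r_squared(predicted, actual) -> float:
    """sum((xhat - xbar)^2) / sum((x - xbar)^2), xbar = mean of actual."""
    p, a = _pair(predicted, actual)
    denom = float(((a - a.mean()) ** 2).sum())
    if denom == 0.0:
        raise UndefinedMetricError("actual values are constant; R^2 undefined")
    return float(((p - a.mean()) ** 2).sum()) / denom


def rmse(predicted, actual) -> float:
    """sqrt(sum((xhat - x)^2) / (n - 1)), in the label's units (g/g here)."""
    p, a = _pair(predicted, actual)
    return float(np.sqrt(((p - a) ** 2).sum() / (p.size - 1)))


@dataclass(frozen=True)
class BoxplotStats:
    q1: float
    q2: float
    q3: float
    iqr: float
    whisker_min: float
    whisker_max: float
    outliers: tuple

    def __post_init__(self):
        if not self.whisker_min <= self.q1 <= self.q2 <= self.q3 <= self.whisker_max:
            raise ValueError("boxplot statistics out of order")


def boxplot_stats(values, whisker_multiplier: float = 1.0) -> BoxplotStats:
    """Quartiles by linear interpolation; whiskers at ``whisker_multiplier x IQR``.

    The default multiplier of 1 (not the conventional 1.5) matches the
    study's definition Min = Q1 - 1*IQR, Max = Q3 + 1*IQR; points outside
    the whiskers are reported as outliers.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError(f"need at least 4 values for quartiles, got {v.size}")
    q1, q2, q3 = (float(q) for q in np.percentile(v, [25, 50, 75], method="linear"))
    iqr = q3 - q1
    wmin = q1 - whisker_multiplier * iqr
    wmax = q3 + whisker_multiplier * iqr
    outliers = tuple(float(x) for x in np.sort(v[(v < wmin) | (v > wmax)]))
    return BoxplotStats(q1=q1, q2=q2, q3=q3, iqr=iqr,
                        whisker_min=wmin, whisker_max=wmax, outliers=outliers)


@dataclass
class EvalReport:
    dataset_name: str
    split: str
    r_squared: float
    rmse: float
    n: int
    per_ratio: dict = field(default_factory=dict)  # ratio -> BoxplotStats

    def to_json(self) -> str:
        d = {"dataset_name": self.dataset_name, "split": self.split,
             "r_squared": self.r_squared, "rmse": self.rmse, "n": self.n,
             "per_ratio": {str(k): vars(v) | {"outliers": list(v.outliers)}
                           for k, v in self.per_ratio.items()}}
        return json.dumps(d, indent=2)


def evaluate_model(model, dataset, group_by_ratio: bool = True,
                   dataset_name: str = "", split: str = "", batch_size: int = 64,
                   out_json=None, out_figure=None) -> EvalReport:
    """R^2 / RMSE of a model on a materialized split, plus per-ratio boxplot stats.

    ``dataset`` is an :class:`mincenet.pipeline.ImageDataset` (images, labels
    and sample ids).  Predictions are clipped to [0, 1] before scoring, the
    reporting-time convention for a mass fraction.
    """
    from .pipeline import predict_content  # local import to avoid a cycle

    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty split")
    preds = predict_content(model, dataset.images, batch_size=batch_size)
    actual = dataset.labels
    report = EvalReport(
        dataset_name=dataset_name or getattr(dataset, "name", ""),
        split=split,
        r_squared=r_squared(preds, actual),
        rmse=rmse(preds, actual),
        n=len(dataset),
    )
    if group_by_ratio:
        for ratio in sorted(set(float(r) for r in actual)):
            report.per_ratio[float(ratio)] = boxplot_stats(preds[actual == ratio])
    if out_json is not None:
        Path(out_json).write_text(report.to_json())
    if out_figure is not None:
        _boxplot_figure(preds, actual, Path(out_figure))
    return report


def _boxplot_figure(preds, actual, path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ratios = sorted(set(float(r) for r in actual))
    groups = [preds[actual == r] for r in ratios]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(groups, tick_labels=[f"{r:g}" for r in ratios], whis=(0, 100))
    for i, (r, g) in enumerate(zip(ratios, groups), start=1):
        stats = boxplot_stats(g)
        ax.hlines([stats.whisker_min, stats.whisker_max], i - 0.2, i + 0.2,
                  colors="tab:gray", linestyles=":")
    ax.set_xlabel("true adulteration ratio (g/g)")
    ax.set_ylabel("predicted ratio (g/g)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
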