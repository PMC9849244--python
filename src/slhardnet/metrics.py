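"""Confusion-count based evaluation: Dice, Jaccard, accuracy,
sensitivity, specificity.

When the reference class of a ratio is empty the convention is: 1 if the
prediction agrees (nothing to find, nothing found), else 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["ConfusionCounts", "confusion", "metric_report",
           "evaluate_masks", "METRIC_NAMES"]

METRIC_NAMES = ("DIC", "JAC", "ACC", "SEN", "SPE")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a binary prediction vs ground truth."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError(
            f"prediction {pred.shape} and ground truth {gt.shape} differ")
    for name, arr in (("prediction", pred), ("ground truth", gt)):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name} must be binary {{0, 1}}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num: int, den: int, agree: bool) -> float:
    if den == 0:
        return 1.0 if agree else 0.0
    return num / den


def metric_report(c: ConfusionCounts) -> dict[str, float]:
    """DIC/JAC/ACC/SEN/SPE from confusion counts."""
    agree_pos = c.fp == 0 and c.fn == 0
    return {
        "DIC": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, agree_pos),
        "JAC": _ratio(c.tp, c.tp + c.fp + c.fn, agree_pos),
        "ACC": _ratio(c.tp + c.tn, c.total, True),
        "SEN": _ratio(c.tp, c.tp + c.fn, c.fp == 0),
        "SPE": _ratio(c.tn, c.tn + c.fp, c.fn == 0),
    }


def evaluate_masks(preds, gts, ids=None, pooled: bool = False) -> pd.DataFrame:
    """Per-image metric table with a trailing ``mean`` summary row.

    ``pooled=True`` additionally aggregates the raw counts over the whole set
    before computing the summary (challenge-style reporting averages
    per-image metrics instead; that is the default summary).
    """
    rows = []
    totals = ConfusionCounts(0, 0, 0, 0)
    ids = ids if ids is not None else [f"img{i:04d}" for i in range(len(preds))]
    for sid, pred, gt in zip(ids, preds, gts):
        c = confusion(pred, gt)
        totals = totals + c
        rows.append({"id": sid, **metric_report(c)})
    frame = pd.DataFrame(rows)
    if pooled:
        summary = {"id": "pooled", **metric_report(totals)}
    else:
        summary = {"id": "mean",
                   **{m: float(frame[m].mean()) for m in METRIC_NAMES}}
    return pd.concat([frame, pd.DataFrame([summary])], ignore_index=True)


def write_metrics_csv(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.6f")


def boxplot_metric(frames: dict[str, pd.DataFrame], metric: str,
                   path) -> None:
    """Box plot of one per-image metric across variants (e.g. losses).

    ``frames`` maps a label to an ``evaluate_masks`` table; the summary row
    is dropped. Mean values are drawn as dashed lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, series = [], []
    for label, frame in frames.items():
        vals = frame[~frame["id"].isin(("mean", "pooled"))][metric]
        labels.append(label)
        series.append(vals.to_numpy())
    fig, ax = plt.subplots(figsize=(1.8 * len(labels) + 1.5, 4.0))
    ax.boxplot(series, tick_labels=labels, showmeans=True,
               meanline=True, meanprops={"linestyle": "--", "color": "green"})
    ax.set_ylabel(metric)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
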