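"""Confusion-matrix performance metrics.

Per-class values use one-vs-rest definitions; the "overall" row of each
metric is the unweighted macro mean over classes, except accuracy, which
is the global fraction of correct predictions.  Geometric mean is
sqrt(sensitivity * specificity) per class.  Cells with a zero
denominator are reported as NaN (undefined), never silently 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "classification_metrics", "format_metrics_table"]


@dataclass
class ConfusionMatrix:
    """K x K count table, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @classmethod
    def from_labels(cls, y_true, y_pred, class_names=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if class_names is None:
            class_names = [str(c) for c in np.unique(np.concatenate([y_true, y_pred]))]
        pos = {c: i for i, c in enumerate(class_names)}
        counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[pos[str(t)], pos[str(p)]] += 1
        return cls(counts=counts, class_names=list(class_names))

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy plus per-class and macro sensitivity, specificity,
    precision, F1 and geometric mean, as fractions in [0, 1].
    """
    counts = cm.counts
    k = counts.shape[0]
    if k < 2:
        raise ValueError("need at least 2 classes")
    total = counts.sum()
    per_class: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        f1 = _safe_div(2 * prec * sens, prec + sens) if prec + sens else float("nan")
        gmean = float(np.sqrt(sens * spec))
        per_class[name] = {
            "sensitivity": sens,
            "specificity": spec,
            "precision": prec,
            "f1": f1,
            "geometric_mean": gmean,
        }
    overall = {
        m: float(np.mean([per_class[c][m] for c in cm.class_names]))
        for m in ("sensitivity", "specificity", "precision", "f1", "geometric_mean")
    }
    overall["accuracy"] = _safe_div(np.trace(counts), total)
    return {"per_class": per_class, "overall": overall}


def _pct(x: float) -> str:
    if np.isnan(x):
        return "undefined"
    return str(Decimal(str(100 * x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_metrics_table(cm: ConfusionMatrix, metrics: dict | None = None) -> str:
    """Text table of percentages to 2 decimals (half-up rounding)."""
    if metrics is None:
        metrics = classification_metrics(cm)
    lines = ["Metric              Class       Result (%)"]
    rows: list[tuple[str, str, float]] = [("Accuracy", "Overall", metrics["overall"]["accuracy"])]
    for m in ("sensitivity", "specificity", "precision", "f1", "geometric_mean"):
        for c in cm.class_names:
            rows.append((m, c, metrics["per_class"][c][m]))
        rows.append((m, "Overall", metrics["overall"][m]))
    for m, c, v in rows:
        lines.append(f"{m:<20}{c:<12}{_pct(v)}")
    return "\n".join(lines)
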