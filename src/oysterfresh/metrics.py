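"""Confusion-matrix evaluation of the 4-level graders.

Rows are actual levels, columns predicted levels.  Derived per-level
metrics follow the standard one-vs-rest definitions:

* precision_k = TP_k / column-sum_k
* recall_k (sensitivity) = TP_k / row-sum_k
* specificity_k = TN_k / (TN_k + FP_k)
* F1_k = harmonic mean of precision and recall

and overall accuracy = trace / total, which equals the
support-weighted mean of the recalls.  A zero denominator yields NaN
(undefined), never 0.  Percentages display at 2 decimal places.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

N_LEVELS = 4


class MetricsError(ValueError):
    """Invalid input to the evaluation routines."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 actual-by-predicted count table."""

    counts: np.ndarray  # (4, 4) int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (N_LEVELS, N_LEVELS):
            raise MetricsError(f"expected a {N_LEVELS}x{N_LEVELS} matrix, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise MetricsError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-level actual counts (row sums)."""
        return self.counts.sum(axis=1)

    def to_text(self) -> str:
        header = "actual\\pred " + " ".join(f"L{j}".rjust(6) for j in range(1, 5))
        lines = [header]
        for i in range(N_LEVELS):
            lines.append(
                f"L{i + 1}".ljust(12)
                + " ".join(str(int(v)).rjust(6) for v in self.counts[i])
            )
        return "\n".join(lines)

    def to_heatmap(self, path, title: str = "Confusion matrix") -> None:
        """Render the count table as a heat-map PNG."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(self.counts, cmap="Blues")
        for i in range(N_LEVELS):
            for j in range(N_LEVELS):
                ax.text(j, i, int(self.counts[i, j]), ha="center", va="center")
        ax.set_xticks(range(N_LEVELS), [f"L{j}" for j in range(1, 5)])
        ax.set_yticks(range(N_LEVELS), [f"L{i}" for i in range(1, 5)])
        ax.set_xlabel("predicted level")
        ax.set_ylabel("actual level")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion_from_predictions(
    actual: Sequence[int], predicted: Sequence[int]
) -> ConfusionMatrix:
    """Count actual-vs-predicted level pairs into a 4x4 matrix."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape or a.ndim != 1:
        raise MetricsError("actual and predicted must be equal-length 1-D sequences")
    if a.size == 0:
        raise MetricsError("no predictions to evaluate")
    for name, v in (("actual", a), ("predicted", p)):
        if v.min() < 1 or v.max() > N_LEVELS:
            raise MetricsError(f"{name} labels must lie in 1..{N_LEVELS}")
    counts = _sk_confusion(a, p, labels=[1, 2, 3, 4])
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class MetricsReport:
    """Per-level rates plus overall accuracy, all as fractions in [0, 1]."""

    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """Percentage table rounded for display (2 dp, F1 as a ratio)."""
        return pd.DataFrame(
            {
                "level": [1, 2, 3, 4],
                "precision_pct": np.round(self.precision * 100, 2),
                "recall_pct": np.round(self.recall * 100, 2),
                "specificity_pct": np.round(self.specificity * 100, 2),
                "f1": np.round(self.f1, 2),
                "accuracy_pct": np.round(self.accuracy * 100, 2),
            }
        )

    def to_json(self) -> str:
        def lst(x):
            return [None if np.isnan(v) else float(v) for v in x]

        return json.dumps(
            {
                "precision": lst(self.precision),
                "recall": lst(self.recall),
                "specificity": lst(self.specificity),
                "f1": lst(self.f1),
                "accuracy": float(self.accuracy),
            },
            indent=2,
        )


def metrics_from_confusion(matrix: ConfusionMatrix) -> MetricsReport:
    """Derive the standard one-vs-rest metrics from a confusion matrix."""
    c = matrix.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise MetricsError("all-zero confusion matrix")
    diag = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(row > 0, diag / row, np.nan)
        tn = total - row - col + diag
        actual_neg = total - row
        specificity = np.where(actual_neg > 0, tn / actual_neg, np.nan)
        f1 = np.where(
            (precision + recall) > 0,
            2 * precision * recall / (precision + recall),
            np.nan,
        )
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        accuracy=float(diag.sum() / total),
    )


def recompose_overall_accuracy(
    per_level_recalls: Sequence[float], supports: Sequence[int]
) -> float:
    """Overall accuracy from per-level recalls and test supports.

    Recovers the diagonal counts by rounding recall_k x support_k to
    the nearest integer, then divides their sum by the total support.
    Recalls may be given as fractions in [0, 1] or as percentages.
    """
    r = np.asarray(per_level_recalls, dtype=float)
    s = np.asarray(supports, dtype=float)
    if r.shape != (N_LEVELS,) or s.shape != (N_LEVELS,):
        raise MetricsError(f"need {N_LEVELS} recalls and {N_LEVELS} supports")
    if np.any(s <= 0):
        raise MetricsError("supports must be positive")
    if np.any(r > 1.0):
        r = r / 100.0
    if np.any((r < 0) | (r > 1)):
        raise MetricsError("recalls must lie in [0, 1] (or [0, 100] as percent)")
    diag = np.round(r * s)
    return float(diag.sum() / s.sum())
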