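"""Segmentation evaluation: confusion matrix, per-class and aggregate
metrics, IoU, and box-plot / descriptive summaries.

Per-class scores are one-vs-rest over the pixel confusion matrix:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 * P * R / (P + R)          IoU = TP / (TP + FP + FN)

F1 is the harmonic mean of precision and recall; a non-standard variant
``P * R / (P + R)`` (half the harmonic mean) is available behind
``harmonic=False`` for exactness-of-record, but every table this module
renders uses the harmonic form — the only form consistent with its own
aggregate rows. Zero denominators yield 0, except the IoU of two empty
sets, which is 1. ``accuracy`` is the trace over the grand total; macro
averages are unweighted class means and weighted averages use class
support (ground-truth pixel count) as weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np

from .io_dataset import CLASS_ORDER, DimensionMismatchError, Label, LabelMask

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "BoxplotSummary",
    "confusion",
    "precision_recall_f1",
    "report",
    "aggregate_rows",
    "iou",
    "iou_from_cm",
    "boxplot_summary",
    "summarize_scores",
    "round_half_up",
    "render_report",
    "write_report_csv",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, applied only at presentation time."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """3x3 pixel counts; rows = actual class, columns = predicted class,
    both in :data:`~sargamap.io_dataset.CLASS_ORDER` order."""

    counts: np.ndarray
    classes: tuple[Label, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.classes)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: Label) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class."""
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def support(self, cls: Label) -> int:
        return int(self.counts[self.classes.index(cls), :].sum())


@dataclass
class MetricReport:
    per_class: dict[Label, dict[str, float]]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    total: int


@dataclass
class BoxplotSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    lower_whisker: float
    upper_whisker: float
    outliers: list[float]


def confusion(truth: LabelMask, pred: LabelMask) -> ConfusionMatrix:
    """Pixel-wise confusion matrix between ground truth and prediction."""
    if truth.shape != pred.shape:
        raise DimensionMismatchError(f"truth {truth.shape} vs pred {pred.shape}")
    idx = {lab: i for i, lab in enumerate(CLASS_ORDER)}
    remap = np.zeros(3, dtype=np.int64)
    for lab in Label:
        remap[lab] = idx[lab]
    t = remap[truth.labels.ravel()]
    p = remap[pred.labels.ravel()]
    counts = np.bincount(3 * t + p, minlength=9).reshape(3, 3)
    return ConfusionMatrix(counts=counts)


def _f1(p: float, r: float, harmonic: bool) -> float:
    if p + r == 0:
        return 0.0
    return (2.0 if harmonic else 1.0) * p * r / (p + r)


def precision_recall_f1(
    cm: ConfusionMatrix, cls: Label, harmonic: bool = True
) -> dict[str, float]:
    """One-vs-rest precision, recall, and F1 for a class.

    Zero-denominator convention: a metric whose denominator is 0 is 0.
    """
    tp, fp, fn, _ = cm.one_vs_rest(cls)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": p, "recall": r, "f1": _f1(p, r, harmonic)}


def iou_from_cm(cm: ConfusionMatrix, cls: Label) -> float:
    tp, fp, fn, _ = cm.one_vs_rest(cls)
    union = tp + fp + fn
    if union == 0:
        return 1.0
    return tp / union


def iou(truth: LabelMask, pred: LabelMask, cls: Label) -> float:
    """Jaccard coefficient |A∩B| / |A∪B| for one class's pixel sets.

    Defined as 1 when both sets are empty and 0 when exactly one is.
    """
    if truth.shape != pred.shape:
        raise DimensionMismatchError(f"truth {truth.shape} vs pred {pred.shape}")
    a = truth.labels == int(cls)
    b = pred.labels == int(cls)
    inter = int((a & b).sum())
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return inter / union


def report(cm: ConfusionMatrix, harmonic: bool = True) -> MetricReport:
    """Full evaluation-table report from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[Label, dict[str, float]] = {}
    for cls in cm.classes:
        row = precision_recall_f1(cm, cls, harmonic=harmonic)
        row["iou"] = iou_from_cm(cm, cls)
        row["support"] = cm.support(cls)
        per_class[cls] = row
    agg = aggregate_rows(per_class)
    return MetricReport(
        per_class=per_class,
        accuracy=float(np.trace(cm.counts)) / cm.total,
        macro_avg=agg["macro_avg"],
        weighted_avg=agg["weighted_avg"],
        total=cm.total,
    )


def aggregate_rows(
    per_class: dict[Label, dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Macro and support-weighted averages from per-class metric rows.

    Accepts rows with keys precision/recall/f1/support — e.g. the rows of
    a printed evaluation table — independent of any confusion matrix.
    """
    keys = ("precision", "recall", "f1")
    rows = list(per_class.values())
    supports = np.array([r["support"] for r in rows], dtype=np.float64)
    total = supports.sum()
    if total <= 0:
        raise ValueError("total support must be positive")
    macro = {k: float(np.mean([r[k] for r in rows])) for k in keys}
    weighted = {
        k: float(np.sum([r[k] * s for r, s in zip(rows, supports)]) / total)
        for k in keys
    }
    return {"macro_avg": macro, "weighted_avg": weighted}


def boxplot_summary(values: list[float] | np.ndarray) -> BoxplotSummary:
    """Five-number summary with Tukey whiskers.

    Quartiles by linear interpolation between order statistics; whiskers
    at the most extreme data points within 1.5 * IQR of the box; points
    beyond the whiskers are outliers.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    lower_whisker = float(inside.min())
    upper_whisker = float(inside.max())
    outliers = sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotSummary(
        minimum=float(v.min()),
        q1=q1,
        median=med,
        q3=q3,
        maximum=float(v.max()),
        lower_whisker=lower_whisker,
        upper_whisker=upper_whisker,
        outliers=outliers,
    )


def summarize_scores(
    per_image: list[dict[str, float]],
) -> dict[str, dict[str, float]]:
    """Descriptive statistics of per-image scores, one column per metric.

    Rows: mean, sd (sample, ddof=1), min, 25 %, 50 %, 75 %, max — the
    layout of the validation-set summary tables.
    """
    if len(per_image) < 2:
        raise ValueError("need at least 2 per-image score rows for sd")
    out: dict[str, dict[str, float]] = {}
    for key in per_image[0]:
        v = np.asarray([row[key] for row in per_image], dtype=np.float64)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out[key] = {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "min": float(v.min()),
            "25%": float(q1),
            "50%": float(med),
            "75%": float(q3),
            "max": float(v.max()),
        }
    return out


# ---------------------------------------------------------------------------
# rendering

_CLASS_NAMES = {
    Label.SARGASSUM: "Sargassum",
    Label.OTHER: "Other",
    Label.SAND: "Sand",
}


def _rows(rep: MetricReport) -> list[list[str]]:
    rows = [["", "precision", "recall", "f1-score", "support"]]
    fmt = lambda x: f"{round_half_up(x, 2):.2f}"  # noqa: E731
    for cls in rep.per_class:
        r = rep.per_class[cls]
        rows.append(
            [
                _CLASS_NAMES[cls],
                fmt(r["precision"]),
                fmt(r["recall"]),
                fmt(r["f1"]),
                str(int(r["support"])),
            ]
        )
    rows.append(["accuracy", "", "", fmt(rep.accuracy), str(rep.total)])
    for name, agg in (("macro avg", rep.macro_avg), ("weighted avg", rep.weighted_avg)):
        rows.append(
            [name, fmt(agg["precision"]), fmt(agg["recall"]), fmt(agg["f1"]), ""]
        )
    return rows


def render_report(rep: MetricReport) -> str:
    """Aligned text table in the class / accuracy / macro / weighted layout."""
    rows = _rows(rep)
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    return "\n".join(
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in rows
    )


def write_report_csv(rep: MetricReport, path: Path | str) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(_rows(rep))
    return path
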