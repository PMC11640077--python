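"""Per-tooth segmentation metrics, macro averages and the pixel confusion
matrix.

Each tooth channel is scored as an independent binary segmentation problem:
pixel counts (TP/FP/FN/TN) are pooled over all evaluated images per tooth
("micro per tooth"), metrics are computed from the pooled counts, and the
report's Average row is the unweighted mean over the 32 teeth.  All fractions
are reported on the percent scale.

Metric definitions (per tooth, from pooled counts):

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)                IoU = TP / (TP + FP + FN)
    accuracy = (TP + TN) / total

F1 (Dice) and IoU (Jaccard) computed from the same counts obey the identity
IoU = F1 / (2 - F1); a metric with a zero denominator is defined as 0 and the
tooth flagged absent, which keeps reports NaN-free when a tooth is missing
from both truth and prediction.

The 33-label confusion matrix reduces the multi-label planes to one label per
pixel: predicted label = argmax over channels with probability above the
threshold (background if none; ties break to the lowest channel index), truth
label = lowest-index truth channel (background if none).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fdi import FDILabelMap, build_fdi_label_map
from .network import PredictionStack, softmax_to_binary, threshold_predictions

__all__ = [
    "BinaryCounts", "ToothMetrics", "MetricsReport",
    "binary_counts", "precision", "recall", "f1", "iou", "accuracy",
    "tooth_metrics", "per_tooth_report", "pixel_confusion_matrix",
    "compare_activations", "macro_average",
    "load_published_sigmoid_table", "load_published_comparison_table",
    "load_published_confusion_matrix",
    "CONFUSION_LABELS",
]

REPORT_COLUMNS = ["F1-Score", "mIoU", "Precision", "Recall", "Acc"]

#: Confusion-matrix label order: background first, then FDI codes ascending.
CONFUSION_LABELS = ["Background"] + [str(c) for c in sorted(build_fdi_label_map().codes)]


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ToothMetrics:
    precision: float
    recall: float
    f1: float
    iou: float
    accuracy: float
    absent: bool = False


def binary_counts(pred: np.ndarray, truth: np.ndarray) -> BinaryCounts:
    """Pixelwise 2x2 tally of two equal-shaped binary planes."""
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if not np.isin(p, (0, 1)).all() or not np.isin(t, (0, 1)).all():
        raise ValueError("binary_counts requires binary planes")
    p = p.astype(bool)
    t = t.astype(bool)
    return BinaryCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def precision(c: BinaryCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def recall(c: BinaryCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def f1(c: BinaryCounts) -> float:
    p, r = precision(c), recall(c)
    return _ratio(2 * p * r, p + r)


def iou(c: BinaryCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def accuracy(c: BinaryCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def tooth_metrics(c: BinaryCounts) -> ToothMetrics:
    absent = (c.tp + c.fp + c.fn) == 0
    return ToothMetrics(precision(c), recall(c), f1(c), iou(c), accuracy(c),
                        absent=absent)


def _stack_planes(stacks) -> np.ndarray:
    """Normalize input to an (N, H, W, 32) binary array."""
    if hasattr(stacks, "planes"):
        arr = stacks.planes[None]
    else:
        arr = np.asarray(stacks)
        if arr.ndim == 3:
            arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 32:
        raise ValueError(f"expected (N, H, W, 32) planes, got {arr.shape}")
    return arr


def per_tooth_counts(pred_stacks, truth_stacks) -> list[BinaryCounts]:
    """Pool per-tooth pixel counts over all evaluated images."""
    pred = _stack_planes(pred_stacks)
    truth = _stack_planes(truth_stacks)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction/truth shape mismatch: {pred.shape} vs {truth.shape}")
    return [binary_counts(pred[..., ch], truth[..., ch]) for ch in range(32)]


@dataclass
class MetricsReport:
    """Per-tooth metric table in the standard report layout plus raw counts."""

    table: pd.DataFrame          # 32 FDI rows + Average row, percent scale
    counts: list[BinaryCounts]

    def row(self, fdi_code: int | str) -> pd.Series:
        return self.table.loc[str(fdi_code)]

    @property
    def average(self) -> pd.Series:
        return self.table.loc["Average"]

    def to_csv(self, path) -> None:
        self.table.round(2).to_csv(path, index_label="Tooth Number")


def per_tooth_report(pred_stacks, truth_stacks,
                     label_map: FDILabelMap | None = None) -> MetricsReport:
    """Score predictions against truth, one row per FDI code plus Average.

    Counts are pooled over the whole evaluated set per tooth before metrics;
    the Average row is the unweighted mean of the 32 per-tooth rows.
    """
    label_map = label_map or build_fdi_label_map()
    counts = per_tooth_counts(pred_stacks, truth_stacks)
    rows = {}
    for ch, c in enumerate(counts):
        m = tooth_metrics(c)
        rows[str(label_map.code_of(ch))] = [
            100 * m.f1, 100 * m.iou, 100 * m.precision, 100 * m.recall,
            100 * m.accuracy,
        ]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=REPORT_COLUMNS)
    df = df.sort_index(key=lambda idx: idx.astype(int))
    df.loc["Average"] = df.mean(axis=0)
    return MetricsReport(table=df, counts=counts)


def macro_average(table: pd.DataFrame) -> pd.Series:
    """Unweighted column means over the per-tooth rows of a report table.

    Any row labeled ``Average`` is excluded before averaging, so the function
    recomputes the macro row from the 32 printed per-tooth values.
    """
    body = table[table.index.astype(str) != "Average"]
    return body.mean(axis=0)


def pixel_confusion_matrix(probs, truth_stacks, t: float = 0.5,
                           label_map: FDILabelMap | None = None) -> pd.DataFrame:
    """33 x 33 single-label pixel tally (rows = truth, columns = predicted).

    ``probs`` is a sigmoid :class:`PredictionStack` or an (N, H, W, 32)
    probability array.  Each pixel's predicted label is the argmax over the
    channels whose probability exceeds ``t`` (Background when none pass;
    ties resolve to the lowest channel index); its truth label is the
    lowest-index truth channel, or Background.
    """
    label_map = label_map or build_fdi_label_map()
    if isinstance(probs, PredictionStack):
        if probs.activation != "sigmoid":
            raise ValueError("confusion matrix expects a sigmoid probability stack")
        probs = probs.probs
    probs = np.asarray(probs)
    if probs.ndim == 3:
        probs = probs[None]
    truth = _stack_planes(truth_stacks)
    if probs.shape != truth.shape:
        raise ValueError(f"probs/truth shape mismatch: {probs.shape} vs {truth.shape}")

    masked = np.where(probs > t, probs, -np.inf)
    pred_ch = masked.argmax(axis=-1)                    # lowest index wins ties
    pred_bg = ~(probs > t).any(axis=-1)
    truth_ch = truth.argmax(axis=-1)
    truth_bg = truth.sum(axis=-1) == 0

    # map channel -> position in the FDI-sorted label list (offset by 1 for bg)
    order = np.argsort([label_map.code_of(ch) for ch in range(32)])
    chan_to_label = np.empty(32, dtype=np.intp)
    chan_to_label[order] = np.arange(1, 33)

    pred_lab = np.where(pred_bg, 0, chan_to_label[pred_ch])
    truth_lab = np.where(truth_bg, 0, chan_to_label[truth_ch])
    counts = np.bincount(truth_lab.ravel() * 33 + pred_lab.ravel(),
                         minlength=33 * 33).reshape(33, 33)
    return pd.DataFrame(counts, index=CONFUSION_LABELS, columns=CONFUSION_LABELS)


@dataclass
class ActivationComparison:
    """Side-by-side per-tooth F1/mIoU of a sigmoid and a softmax head."""

    sigmoid_report: MetricsReport
    softmax_report: MetricsReport

    @property
    def table(self) -> pd.DataFrame:
        sig = self.sigmoid_report.table
        soft = self.softmax_report.table
        return pd.DataFrame({
            "Sigmoid F1-Score": sig["F1-Score"],
            "Sigmoid mIoU": sig["mIoU"],
            "SoftMax F1-Score": soft["F1-Score"],
            "SoftMax mIoU": soft["mIoU"],
        })


def compare_activations(images, truth_stacks, sigmoid_model, softmax_model,
                        threshold: float = 0.5) -> ActivationComparison:
    """Evaluate two heads on the same test set.

    The sigmoid head is thresholded per channel (overlap preserved); the
    softmax head is reduced by per-pixel argmax (one label per pixel), which
    is exactly the structural handicap it carries on overlapping teeth.
    """
    if sigmoid_model.config.activation != "sigmoid":
        raise ValueError("first model must use the sigmoid head")
    if softmax_model.config.activation != "softmax":
        raise ValueError("second model must use the softmax head")
    imgs = np.asarray(images, dtype=np.float32)
    sig_pred = threshold_predictions(sigmoid_model.forward(imgs), threshold)
    soft_pred = softmax_to_binary(softmax_model.forward(imgs))
    return ActivationComparison(
        sigmoid_report=per_tooth_report(sig_pred, truth_stacks),
        softmax_report=per_tooth_report(soft_pred, truth_stacks),
    )


# ---------------------------------------------------------------------------
# published report tables (transcribed printed values, percent scale)
# ---------------------------------------------------------------------------

def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("toothseg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col="Tooth Number").rename(index=str)


def load_published_sigmoid_table() -> pd.DataFrame:
    """Published per-tooth sigmoid-head results (32 rows + printed Average)."""
    return _load_csv("published_sigmoid_per_tooth.csv")


def load_published_comparison_table() -> pd.DataFrame:
    """Published sigmoid-vs-softmax per-tooth F1/mIoU comparison."""
    return _load_csv("published_activation_comparison.csv")


def load_published_confusion_matrix() -> pd.DataFrame:
    """Published 33x33 pixel confusion matrix (rows = truth labels)."""
    return _load_csv("published_confusion_matrix.csv")
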