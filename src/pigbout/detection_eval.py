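"""Object-detection evaluation: IoU matching, P/R/F1, AP, mAP50, confusion.

Predicted boxes are scored against expert ground-truth boxes per image.
A prediction is a true positive when it is greedily matched (descending
confidence, each ground truth used at most once) to a same-class ground
truth with intersection-over-union at or above the threshold, 0.5 by
default.  Average precision uses all-point interpolation of the
precision-recall curve swept over the confidence ranking; mAP50 is the
unweighted mean of per-class AP at IoU 0.5.  The confusion matrix uses
class-agnostic best-IoU assignment so that class confusions, missed
ground truths (background row) and spurious predictions (background
column) are all visible.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .detection_io import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    BehaviorClass,
    BoundingBox,
)

__all__ = [
    "GroundTruthBox",
    "PredictedBox",
    "iou",
    "match_predictions",
    "MatchResult",
    "precision_recall_f1",
    "f1_from_pr",
    "average_precision",
    "mean_average_precision",
    "confusion_matrix",
    "normalize_confusion",
    "ClassEval",
    "EvalReport",
    "evaluate",
    "read_box_csv",
    "write_box_csv",
]


@dataclass(frozen=True, slots=True)
class GroundTruthBox:
    image_id: str
    class_label: BehaviorClass
    box: BoundingBox


@dataclass(frozen=True, slots=True)
class PredictedBox:
    image_id: str
    class_label: BehaviorClass
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over union area; symmetric, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class MatchResult:
    """TP/FP labels per prediction, in descending-confidence order."""

    order: np.ndarray  # indices into the input predictions, conf-descending
    is_tp: np.ndarray  # bool per ordered prediction
    n_unmatched_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())


def _conf_order(preds: Sequence[PredictedBox]) -> list[int]:
    # stable: ties in confidence keep input order
    return sorted(range(len(preds)), key=lambda i: -preds[i].confidence)


def match_predictions(
    preds: Sequence[PredictedBox],
    gts: Sequence[GroundTruthBox],
    iou_thr: float = 0.5,
) -> MatchResult:
    """Greedy class-aware matching in descending confidence.

    Each prediction may claim the unmatched same-class, same-image
    ground truth of highest IoU, provided IoU >= ``iou_thr``; each
    ground truth is claimed at most once.
    """
    order = _conf_order(preds)
    gt_taken = [False] * len(gts)
    is_tp = np.zeros(len(preds), dtype=bool)
    for rank, i in enumerate(order):
        p = preds[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if (
                gt_taken[j]
                or g.image_id != p.image_id
                or g.class_label is not p.class_label
            ):
                continue
            v = iou(p.box, g.box)
            if v >= iou_thr and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            gt_taken[best_j] = True
            is_tp[rank] = True
    return MatchResult(
        order=np.asarray(order, dtype=int),
        is_tp=is_tp,
        n_unmatched_gt=gt_taken.count(False),
    )


@dataclass(frozen=True)
class PRF1:
    precision: float | None
    recall: float | None
    f1: float | None


def precision_recall_f1(tp: int, fp: int, fn: int) -> PRF1:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R).

    A statistic whose denominator is zero is reported as ``None``
    (undefined), and F1 is ``None`` when either component is.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f1 = None
    if precision is not None and recall is not None:
        f1 = f1_from_pr(precision, recall)
    return PRF1(precision, recall, f1)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def average_precision(
    preds: Sequence[PredictedBox],
    gts: Sequence[GroundTruthBox],
    class_label: BehaviorClass,
    iou_thr: float = 0.5,
) -> float | None:
    """All-point interpolated AP for one class at the given IoU threshold.

    The precision-recall curve is traced by sweeping the
    confidence-ranked predictions of the class (no confidence cut);
    AP integrates the monotone precision envelope over recall.
    Returns ``None`` (with a warning) when the class has no ground
    truth; 0.0 when it has ground truth but no predictions.
    """
    cls_gts = [g for g in gts if g.class_label is class_label]
    if not cls_gts:
        warnings.warn(
            f"AP undefined for {class_label.value}: no ground-truth boxes",
            stacklevel=2,
        )
        return None
    cls_preds = [p for p in preds if p.class_label is class_label]
    if not cls_preds:
        return 0.0
    match = match_predictions(cls_preds, cls_gts, iou_thr=iou_thr)
    tp_cum = np.cumsum(match.is_tp)
    fp_cum = np.cumsum(~match.is_tp)
    recall = tp_cum / len(cls_gts)
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (monotone non-increasing from the right)
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mrec = np.concatenate(([0.0], recall, [1.0]))
    for k in range(len(mpre) - 2, -1, -1):
        mpre[k] = max(mpre[k], mpre[k + 1])
    steps = np.flatnonzero(mrec[1:] != mrec[:-1]) + 1
    return float(np.sum((mrec[steps] - mrec[steps - 1]) * mpre[steps]))


def mean_average_precision(
    preds: Sequence[PredictedBox],
    gts: Sequence[GroundTruthBox],
    classes: Sequence[BehaviorClass] = tuple(BehaviorClass),
    iou_thr: float = 0.5,
) -> float | None:
    """Unweighted mean of per-class AP; classes without GT are excluded."""
    aps = [average_precision(preds, gts, c, iou_thr) for c in classes]
    aps = [a for a in aps if a is not None]
    return float(np.mean(aps)) if aps else None


def confusion_matrix(
    preds: Sequence[PredictedBox],
    gts: Sequence[GroundTruthBox],
    iou_thr: float = 0.5,
    conf_thr: float = DEFAULT_CONFIDENCE_THRESHOLD,
    classes: Sequence[BehaviorClass] = tuple(BehaviorClass),
) -> np.ndarray:
    """(K+1) x (K+1) confusion counts; rows = predicted, cols = true.

    Predictions are first filtered at ``conf_thr``.  Within each image,
    prediction-ground-truth pairs with IoU >= ``iou_thr`` are assigned
    greedily by descending IoU regardless of class, so off-diagonal
    entries count localised-but-misclassified boxes.  The final row is
    background (missed ground truths); the final column is background
    (unmatched predictions).
    """
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((k + 1, k + 1), dtype=int)
    kept = [p for p in preds if p.confidence >= conf_thr]
    images = {p.image_id for p in kept} | {g.image_id for g in gts}
    for img in sorted(images):
        img_preds = [p for p in kept if p.image_id == img]
        img_gts = [g for g in gts if g.image_id == img]
        pairs = [
            (iou(p.box, g.box), pi, gi)
            for pi, p in enumerate(img_preds)
            for gi, g in enumerate(img_gts)
        ]
        pairs = [t for t in pairs if t[0] >= iou_thr]
        pairs.sort(key=lambda t: -t[0])
        p_taken, g_taken = set(), set()
        for _, pi, gi in pairs:
            if pi in p_taken or gi in g_taken:
                continue
            p_taken.add(pi)
            g_taken.add(gi)
            m[idx[img_preds[pi].class_label], idx[img_gts[gi].class_label]] += 1
        for pi, p in enumerate(img_preds):
            if pi not in p_taken:
                m[idx[p.class_label], k] += 1
        for gi, g in enumerate(img_gts):
            if gi not in g_taken:
                m[k, idx[g.class_label]] += 1
    return m


def normalize_confusion(matrix: np.ndarray) -> np.ndarray:
    """Column-normalised confusion matrix (each true class sums to 1)."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, matrix / sums, 0.0)
    return out


@dataclass(frozen=True)
class ClassEval:
    class_label: BehaviorClass
    n_gt: int
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None
    ap50: float | None


@dataclass(frozen=True)
class EvalReport:
    per_class: dict[BehaviorClass, ClassEval]
    map50: float | None


def evaluate(
    preds: Sequence[PredictedBox],
    gts: Sequence[GroundTruthBox],
    iou_thr: float = 0.5,
    conf_thr: float = DEFAULT_CONFIDENCE_THRESHOLD,
    classes: Sequence[BehaviorClass] = tuple(BehaviorClass),
) -> EvalReport:
    """Full per-class report: counts and P/R/F1 at ``conf_thr``, AP on
    the unthresholded ranking, and mAP50 across classes with GT."""
    per_class: dict[BehaviorClass, ClassEval] = {}
    for c in classes:
        cls_gts = [g for g in gts if g.class_label is c]
        cls_preds = [
            p for p in preds
            if p.class_label is c and p.confidence >= conf_thr
        ]
        match = match_predictions(cls_preds, cls_gts, iou_thr=iou_thr)
        tp, fp = match.n_tp, match.n_fp
        fn = len(cls_gts) - tp
        prf = precision_recall_f1(tp, fp, fn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap = average_precision(preds, gts, c, iou_thr) if cls_gts else None
        per_class[c] = ClassEval(
            c, len(cls_gts), tp, fp, fn, prf.precision, prf.recall, prf.f1, ap
        )
    aps = [e.ap50 for e in per_class.values() if e.ap50 is not None]
    return EvalReport(per_class, float(np.mean(aps)) if aps else None)


# ---------------------------------------------------------------------------
# Box CSV I/O: `image_id,class,x_min,y_min,x_max,y_max[,confidence]`

def write_box_csv(
    boxes: Iterable[GroundTruthBox | PredictedBox], path: str | Path
) -> None:
    boxes = list(boxes)
    with_conf = any(isinstance(b, PredictedBox) for b in boxes)
    header = ["image_id", "class", "x_min", "y_min", "x_max", "y_max"]
    if with_conf:
        header.append("confidence")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for b in boxes:
            row = [
                b.image_id, b.class_label.value,
                repr(b.box.x_min), repr(b.box.y_min),
                repr(b.box.x_max), repr(b.box.y_max),
            ]
            if with_conf:
                row.append(repr(b.confidence) if isinstance(b, PredictedBox) else "")
            writer.writerow(row)


def read_box_csv(path: str | Path) -> list[GroundTruthBox] | list[PredictedBox]:
    """Read a box table; rows with a confidence column become predictions."""
    out: list = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            box = BoundingBox(
                float(row["x_min"]), float(row["y_min"]),
                float(row["x_max"]), float(row["y_max"]),
            )
            cls = BehaviorClass(row["class"])
            conf = row.get("confidence")
            if conf not in (None, ""):
                out.append(PredictedBox(row["image_id"], cls, box, float(conf)))
            else:
                out.append(GroundTruthBox(row["image_id"], cls, box))
    return out
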