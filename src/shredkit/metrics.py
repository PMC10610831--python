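"""Detection evaluation: precision, recall, AP, mAP@.5 and mAP@.5:.95.

Matching follows the standard YOLO protocol: predictions are processed in
descending confidence; each is a true positive when its best-IoU unmatched
same-class ground truth reaches the IoU threshold, otherwise a false
positive; each truth can be matched at most once.  AP is the area under the
precision-recall curve with all-point interpolation (the precision envelope
made monotone non-increasing and summed over recall increments) — the exact
discrete analogue of the integral definition.  mAP averages per-class APs
over the classes that have ground truth; mAP@.5:.95 additionally averages
over the ten IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CLASS_NAMES, DetectionBox, ValidationError, box_iou_xyxy

IOU_THRESHOLDS_50_95: tuple[float, ...] = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass
class MatchResult:
    """Prediction/truth matching outcome at one IoU threshold."""

    tp: int
    fp: int
    fn: int
    flags: list[bool]  # per prediction, ordered by descending confidence
    confidences: list[float]

    def __post_init__(self) -> None:
        assert self.tp + self.fp == len(self.flags)


@dataclass
class APResult:
    per_class_ap: dict[str, float]  # AP at IoU 0.5, classes with truth only
    map50: float
    map50_95: float
    thresholds: tuple[float, ...] = IOU_THRESHOLDS_50_95


def _conf(b: DetectionBox) -> float:
    return 1.0 if b.confidence is None else b.confidence


def match(
    predictions: list[DetectionBox],
    truths: list[DetectionBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching within one image.

    Ties in confidence are broken by input order (stable sort).
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValidationError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(predictions)), key=lambda i: -_conf(predictions[i]))
    matched = [False] * len(truths)
    flags: list[bool] = []
    confs: list[float] = []
    for i in order:
        p = predictions[i]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j] or t.class_index != p.class_index:
                continue
            iou = box_iou_xyxy(p.to_xyxy(), t.to_xyxy())
            if iou > best_iou:
                best_iou, best_j = iou, j
        hit = best_j >= 0 and best_iou >= iou_threshold
        if hit:
            matched[best_j] = True
        flags.append(hit)
        confs.append(_conf(p))
    tp = sum(flags)
    return MatchResult(tp=tp, fp=len(flags) - tp, fn=len(truths) - tp, flags=flags, confidences=confs)


def precision(m: MatchResult) -> float:
    if m.tp + m.fp == 0:
        warnings.warn("precision undefined with no predictions; returning 0", stacklevel=2)
        return 0.0
    return m.tp / (m.tp + m.fp)


def recall(m: MatchResult) -> float:
    if m.tp + m.fn == 0:
        warnings.warn("recall undefined with no ground truth; returning 0", stacklevel=2)
        return 0.0
    return m.tp / (m.tp + m.fn)


def average_precision(flags: list[bool], n_truths: int) -> float:
    """Area under the P-R curve from confidence-ordered TP/FP flags."""
    if n_truths <= 0:
        raise ValidationError("AP undefined without ground truth")
    if not flags:
        return 0.0
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    fp_cum = np.cumsum(~np.asarray(flags, dtype=bool))
    rec = tp_cum / n_truths
    prec = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: monotone precision envelope over recall
    r = np.concatenate(([0.0], rec, [rec[-1]]))
    p = np.concatenate(([1.0], prec, [0.0]))
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


GroupedBoxes = dict[str, list[DetectionBox]]


def _class_flags(
    predictions: GroupedBoxes, truths: GroupedBoxes, class_index: int, tau: float
) -> tuple[list[tuple[float, bool]], int]:
    """Pooled (confidence, flag) pairs and truth count for one class."""
    pairs: list[tuple[float, bool]] = []
    n_truth = 0
    for image_id in sorted(set(predictions) | set(truths)):
        preds = [b for b in predictions.get(image_id, []) if b.class_index == class_index]
        gts = [b for b in truths.get(image_id, []) if b.class_index == class_index]
        n_truth += len(gts)
        m = match(preds, gts, tau) if preds else MatchResult(0, 0, len(gts), [], [])
        pairs.extend(zip(m.confidences, m.flags))
    return pairs, n_truth


def map_range(predictions: GroupedBoxes, truths: GroupedBoxes) -> APResult:
    """mAP@.5 and mAP@.5:.95 over a set of images keyed by image id.

    Classes without any ground truth are excluded from the means.
    """
    per_class: dict[str, float] = {}
    ap_sum_all_tau = 0.0
    n_terms = 0
    for ci, cname in enumerate(CLASS_NAMES):
        aps: list[float] = []
        has_truth = False
        for tau in IOU_THRESHOLDS_50_95:
            pairs, n_truth = _class_flags(predictions, truths, ci, tau)
            if n_truth == 0:
                break
            has_truth = True
            pairs.sort(key=lambda t: -t[0])
            aps.append(average_precision([f for _, f in pairs], n_truth))
        if not has_truth:
            continue
        per_class[cname] = aps[0]
        ap_sum_all_tau += float(np.mean(aps))
        n_terms += 1
    if n_terms == 0:
        return APResult(per_class_ap={}, map50=0.0, map50_95=0.0)
    return APResult(
        per_class_ap=per_class,
        map50=float(np.mean(list(per_class.values()))),
        map50_95=ap_sum_all_tau / n_terms,
    )


def evaluate_detections(
    predictions: GroupedBoxes,
    truths: GroupedBoxes,
    conf_threshold: float = 0.25,
    iou_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-class AP plus dataset precision/recall at a confidence cutoff."""
    ap = map_range(predictions, truths)
    rows = []
    for ci, cname in enumerate(CLASS_NAMES):
        if cname not in ap.per_class_ap:
            continue
        tp = fp = fn = 0
        for image_id in sorted(set(predictions) | set(truths)):
            preds = [
                b
                for b in predictions.get(image_id, [])
                if b.class_index == ci and _conf(b) >= conf_threshold
            ]
            gts = [b for b in truths.get(image_id, []) if b.class_index == ci]
            m = match(preds, gts, iou_threshold)
            tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        rows.append((cname, ap.per_class_ap[cname], prec, rec))
    df = pd.DataFrame(rows, columns=["class", "ap50", "precision", "recall"])
    df.attrs["map50"] = ap.map50
    df.attrs["map50_95"] = ap.map50_95
    return df
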