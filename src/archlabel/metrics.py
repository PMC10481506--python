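"""Detection, segmentation and labeling evaluation.

Conventions follow standard instance-evaluation practice: predicted and
ground-truth detections are matched one-to-one by maximizing total bounding
box IoU (Hungarian assignment) with pairs below an IoU threshold discarded;
point-mask metrics treat tooth as the positive class; FDI labeling accuracy
is the fraction of ground-truth instances whose matched prediction carries
the correct code.  Undefined metrics (zero denominator) are reported as NaN,
never as 0, so per-code means are not biased by absent codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import fdi
from .geometry import ToothDetection, box_iou


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ContingencyCounts) -> dict[str, float]:
    """accuracy, precision, recall and IoU from a 2x2 contingency table.

    accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), IoU = TP/(TP+FP+FN); NaN where undefined.
    """
    return {
        "accuracy": _ratio(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn),
        "precision": _ratio(c.tp, c.tp + c.fp),
        "recall": _ratio(c.tp, c.tp + c.fn),
        "iou": _ratio(c.tp, c.tp + c.fp + c.fn),
    }


@dataclass
class Matching:
    """One-to-one detection correspondence above the IoU threshold."""

    pairs: list[tuple[int, int, float]]      # (pred index, gt index, box IoU)
    unmatched_pred: list[int]
    unmatched_gt: list[int]


def match_detections(
    pred: list[ToothDetection],
    gt: list[ToothDetection],
    iou_threshold: float = 0.5,
) -> Matching:
    """Optimal one-to-one matching of detections by bounding-box IoU."""
    if not pred or not gt:
        return Matching([], list(range(len(pred))), list(range(len(gt))))
    iou = np.array([[box_iou(p.box, g.box) for g in gt] for p in pred])
    rows, cols = linear_sum_assignment(-iou)
    pairs = [
        (int(r), int(c), float(iou[r, c]))
        for r, c in zip(rows, cols)
        if iou[r, c] >= iou_threshold
    ]
    matched_p = {r for r, _, _ in pairs}
    matched_g = {c for _, c, _ in pairs}
    return Matching(
        pairs=pairs,
        unmatched_pred=[i for i in range(len(pred)) if i not in matched_p],
        unmatched_gt=[i for i in range(len(gt)) if i not in matched_g],
    )


def _codes_present(labels: list[int | None]) -> list[int]:
    return sorted({c for c in labels if c is not None})


def detection_metrics(
    matching: Matching,
    pred_labels: list[int | None],
    gt_labels: list[int],
    label_aware: bool = True,
) -> pd.DataFrame:
    """Per-FDI detection precision, recall and mean box IoU.

    Label-aware (default): a matched pair counts as a true positive of code c
    only when prediction and ground truth both carry c.  Label-agnostic: any
    matched pair is a TP of its ground-truth code regardless of the predicted
    label (pure localization quality).
    """
    codes = sorted(set(_codes_present(pred_labels)) | set(gt_labels))
    rows = []
    for code in codes:
        if label_aware:
            tp_pairs = [
                (p, g, i)
                for p, g, i in matching.pairs
                if gt_labels[g] == code and pred_labels[p] == code
            ]
            fp = sum(
                1
                for p, lab in enumerate(pred_labels)
                if lab == code and not any(p == pp for pp, _, _ in tp_pairs)
            )
            fn = sum(
                1
                for g, lab in enumerate(gt_labels)
                if lab == code and not any(g == gg for _, gg, _ in tp_pairs)
            )
        else:
            tp_pairs = [(p, g, i) for p, g, i in matching.pairs if gt_labels[g] == code]
            fp = 0
            fn = sum(1 for g in matching.unmatched_gt if gt_labels[g] == code)
        tp = len(tp_pairs)
        rows.append(
            {
                "code": code,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": _ratio(tp, tp + fp),
                "recall": _ratio(tp, tp + fn),
                "box_iou": float(np.mean([i for _, _, i in tp_pairs]))
                if tp_pairs
                else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("code")


def segmentation_metrics(
    pred_mask: np.ndarray, gt_mask: np.ndarray
) -> tuple[ContingencyCounts, dict[str, float]]:
    """Point-wise tooth/gingiva metrics over one shared point set."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    gt_mask = np.asarray(gt_mask).astype(bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("pred and gt masks must have the same length")
    counts = ContingencyCounts(
        tp=int(np.sum(pred_mask & gt_mask)),
        tn=int(np.sum(~pred_mask & ~gt_mask)),
        fp=int(np.sum(pred_mask & ~gt_mask)),
        fn=int(np.sum(~pred_mask & gt_mask)),
    )
    return counts, classification_metrics(counts)


UNASSIGNED = "unassigned"
SPURIOUS = "spurious"


def labeling_accuracy(
    matching: Matching,
    pred_labels: list[int | None],
    gt_labels: list[int],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-FDI labeling accuracy and per-jaw confusion matrices.

    Accuracy of code c is the fraction of ground-truth instances of c whose
    matched prediction carries c.  The confusion matrices (one per jaw) have
    one row per ground-truth code in arch order plus a 'spurious' row for
    unmatched predictions, and one column per predicted code plus an
    'unassigned' column covering unmatched ground truth, unassigned
    predictions and cross-jaw predictions.
    """
    pred_of_gt: dict[int, int | None] = {}
    for p, g, _ in matching.pairs:
        pred_of_gt[g] = pred_labels[p]

    rows = []
    for code in sorted(set(gt_labels)):
        idx = [g for g, lab in enumerate(gt_labels) if lab == code]
        correct = sum(1 for g in idx if pred_of_gt.get(g) == code)
        rows.append(
            {"code": code, "n": len(idx), "accuracy": _ratio(correct, len(idx))}
        )
    table = pd.DataFrame(rows).set_index("code")

    confusion: dict[str, pd.DataFrame] = {}
    for jaw in (fdi.UPPER, fdi.LOWER):
        order = list(fdi.ARCH_ORDER[jaw])
        mat = pd.DataFrame(
            0,
            index=order + [SPURIOUS],
            columns=order + [UNASSIGNED],
        )
        for g, lab in enumerate(gt_labels):
            if fdi.jaw_of(lab) != jaw:
                continue
            pred = pred_of_gt.get(g)
            col = pred if pred in order else UNASSIGNED
            mat.loc[lab, col] += 1
        for p in matching.unmatched_pred:
            lab = pred_labels[p]
            if lab is not None and fdi.jaw_of(lab) == jaw:
                mat.loc[SPURIOUS, lab] += 1
        confusion[jaw] = mat
    return table, confusion


def evaluate_scene(
    pred_scene,
    gt_scene,
    pred_labels: dict[int, int | None],
    iou_threshold: float = 0.5,
) -> dict:
    """Full Table-style evaluation of one predicted scene against truth.

    ``pred_labels`` maps predicted detection ids to FDI codes (the labeling
    result); the ground-truth scene must carry ``fdi_labels``.  Returns the
    matching, the three metric tables and the confusion matrices.
    """
    if gt_scene.fdi_labels is None:
        raise ValueError("ground-truth scene lacks fdi_labels")
    matching = match_detections(
        pred_scene.detections, gt_scene.detections, iou_threshold
    )
    plabels = [pred_labels.get(d.detection_id) for d in pred_scene.detections]
    glabels = [gt_scene.fdi_labels[d.detection_id] for d in gt_scene.detections]
    det = detection_metrics(matching, plabels, glabels)
    lab, confusion = labeling_accuracy(matching, plabels, glabels)

    seg_rows = []
    for p, g, _ in matching.pairs:
        pd_det = pred_scene.detections[p]
        gt_det = gt_scene.detections[g]
        if (
            pd_det.mask is None
            or gt_det.mask is None
            or pd_det.n_points != gt_det.n_points
        ):
            continue
        counts, m = segmentation_metrics(pd_det.mask, gt_det.mask)
        seg_rows.append({"code": glabels[g], **m})
    seg = (
        pd.DataFrame(seg_rows).groupby("code").mean()
        if seg_rows
        else pd.DataFrame(columns=["accuracy", "precision", "recall", "iou"])
    )
    return {
        "matching": matching,
        "detection": det,
        "segmentation": seg,
        "labeling": lab,
        "confusion": confusion,
    }
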