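"""Scoring of segmentations and spot calls against ground truth.

Detection scoring follows instance-segmentation practice: predicted and
true objects are matched greedily by descending IoU, a match requiring
IoU >= 0.5 (the criterion used for the validation precision figures);
precision = TP/(TP+FP), recall = TP/(TP+FN).  Spot calls are matched by
minimum-cost (Hungarian) assignment gated at a match radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segment import LabelMask


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def iou_matrix(true: LabelMask | np.ndarray, pred: LabelMask | np.ndarray) -> np.ndarray:
    """Pairwise IoU between true and predicted labels.

    Returns an array of shape (n_true, n_pred) indexed by the sorted
    nonzero label ids of each mask.
    """
    t = true.labels if isinstance(true, LabelMask) else np.asarray(true)
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"shapes differ: {t.shape} vs {p.shape}")
    nt, npred = int(t.max(initial=0)), int(p.max(initial=0))
    joint = t.astype(np.int64) * (npred + 1) + p
    counts = np.bincount(joint.ravel(), minlength=(nt + 1) * (npred + 1))
    inter = counts.reshape(nt + 1, npred + 1)[1:, 1:].astype(np.float64)
    area_t = np.bincount(t.ravel(), minlength=nt + 1)[1:]
    area_p = np.bincount(p.ravel(), minlength=npred + 1)[1:]
    union = area_t[:, None] + area_p[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_labels(true: LabelMask | np.ndarray, pred: LabelMask | np.ndarray,
                 iou_threshold: float = 0.5) -> DetectionScore:
    """Greedy IoU matching (highest IoU first, one-to-one) at a threshold."""
    iou = iou_matrix(true, pred)
    n_true, n_pred = iou.shape
    pairs = np.argwhere(iou >= iou_threshold)
    order = np.argsort(-iou[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_t: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for ti, pi in pairs[order]:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(int(ti))
        used_p.add(int(pi))
        tp += 1
    return DetectionScore(tp=tp, fp=n_pred - tp, fn=n_true - tp)


@dataclass
class PointMatchScore:
    tp: int
    fp: int
    fn: int
    rmse_px: float  # over matched pairs; nan when none matched

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def match_points(true_xy: np.ndarray, pred_xy: np.ndarray,
                 radius_px: float = 2.0) -> PointMatchScore:
    """Hungarian matching of predicted to true points within a radius."""
    true_xy = np.asarray(true_xy, dtype=np.float64).reshape(-1, 2)
    pred_xy = np.asarray(pred_xy, dtype=np.float64).reshape(-1, 2)
    if len(true_xy) == 0 or len(pred_xy) == 0:
        return PointMatchScore(0, len(pred_xy), len(true_xy), float("nan"))
    d = np.sqrt(((true_xy[:, None, :] - pred_xy[None, :, :]) ** 2).sum(-1))
    big = radius_px * 1e6
    cost = np.where(d <= radius_px, d, big)
    rows, cols = linear_sum_assignment(cost)
    matched = d[rows, cols] <= radius_px
    tp = int(matched.sum())
    rmse = float(np.sqrt((d[rows, cols][matched] ** 2).mean())) if tp else float("nan")
    return PointMatchScore(tp=tp, fp=len(pred_xy) - tp, fn=len(true_xy) - tp,
                           rmse_px=rmse)


# ---------------------------------------------------------------------------
# Standard validation scenes
# ---------------------------------------------------------------------------

def standard_validation_params(base_seed: int = 0, n_images: int = 5):
    """Simulation parameters of the standard segmentation-validation set:
    five fields with the simulator defaults (25 nuclei and 3 glomerular
    tufts each, standard noise), seeded deterministically from ``base_seed``."""
    from .simulate import TissueSimParams

    return [TissueSimParams(seed=base_seed * 1000 + i) for i in range(n_images)]


def segmentation_validation(base_seed: int = 0, n_images: int = 5,
                            iou_threshold: float = 0.5) -> dict:
    """Score the classical segmenters on the standard validation scenes.

    Returns nucleus/glomerulus precision and recall pooled over the set,
    plus the ground-truth object totals.
    """
    from .segment import segment_glomeruli, segment_nuclei
    from .simulate import simulate_tissue_image

    nuc = DetectionScore(0, 0, 0)
    glo = DetectionScore(0, 0, 0)
    for params in standard_validation_params(base_seed, n_images):
        stack, truth = simulate_tissue_image(params)
        s_n = match_labels(truth.nucleus_mask, segment_nuclei(stack), iou_threshold)
        s_g = match_labels(truth.glom_mask, segment_glomeruli(stack), iou_threshold)
        nuc = DetectionScore(nuc.tp + s_n.tp, nuc.fp + s_n.fp, nuc.fn + s_n.fn)
        glo = DetectionScore(glo.tp + s_g.tp, glo.fp + s_g.fp, glo.fn + s_g.fn)
    return {
        "n_true_nuclei": nuc.tp + nuc.fn,
        "n_true_glomeruli": glo.tp + glo.fn,
        "nucleus_precision": nuc.precision,
        "nucleus_recall": nuc.recall,
        "glomerulus_precision": glo.precision,
        "glomerulus_recall": glo.recall,
    }
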