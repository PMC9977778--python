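"""Evaluation against ground-truth lesion masks.

Two complementary accountings are provided, because sensitivity/specificity
for a lesion detector can be read at either granularity:

* **region level** — connected components (8-connectivity) of the predicted
  and ground-truth masks are matched one-to-one by intersection-over-union
  (called IOO here); a ground-truth region matched at or above the IOO
  threshold (default 0.8) is a true positive, unmatched ground-truth regions
  are false negatives and unmatched predictions false positives.  A
  region-level true-negative count is ill-posed and is not reported.
* **pixel level** — TP/FP/TN/FN are counted per pixel inside a region of
  interest (normally the field-of-view mask), from which SE = TP/(TP+FN),
  SP = TN/(TN+FP) and ACC = (TP+TN)/total follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "EvalReport",
    "regions_from_mask",
    "ioo",
    "match_regions",
    "pixel_confusion",
    "evaluate_masks",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class EvalReport:
    """Confusion counts and derived rates for one image.

    Pixel-level fields are always present; the region-level fields are
    populated by :func:`evaluate_masks`.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    se: float
    sp: float
    acc: float
    mean_ioo: Optional[float] = None
    per_region_ioo: list = field(default_factory=list)
    region_tp: Optional[int] = None
    region_fp: Optional[int] = None
    region_fn: Optional[int] = None


def regions_from_mask(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """Connected components of a binary mask under 8-connectivity, each as a
    set of (row, col) pixels."""
    labels, n = ndimage.label(np.asarray(mask, dtype=bool),
                              structure=_EIGHT_CONN)
    out = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        out.append({(int(r), int(c)) for r, c in zip(rows, cols)})
    return out


def _as_set(region) -> set[tuple[int, int]]:
    if isinstance(region, set):
        return region
    arr = np.asarray(region)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("a region must be a set of (row, col) or an (N, 2) array")
    return {(int(r), int(c)) for r, c in arr}


def ioo(pred_region, gt_region) -> float:
    """Intersection over union of two pixel regions:
    ``|pred ∩ gt| / (|gt| + |pred| − |pred ∩ gt|)``.

    Undefined (raises ``ValueError``) when both regions are empty.
    """
    pred = _as_set(pred_region)
    gt = _as_set(gt_region)
    union = len(pred) + len(gt) - len(pred & gt)
    if union == 0:
        raise ValueError("IOO is undefined for two empty regions")
    return len(pred & gt) / union


def match_regions(pred_regions: Sequence, gt_regions: Sequence,
                  ioo_threshold: float = 0.8
                  ) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """Greedy one-to-one matching of predicted to ground-truth regions.

    Candidate pairs with IOO >= ``ioo_threshold`` are taken in order of
    descending IOO (ties broken by smaller predicted-region area, then scan
    order), each region matched at most once.  Returns ``(tp, fp, fn,
    matches)`` with matches as ``(gt_index, pred_index, ioo)`` triples.
    """
    if not (0.0 < ioo_threshold <= 1.0):
        raise ValueError("ioo_threshold must lie in (0, 1]")
    preds = [_as_set(r) for r in pred_regions]
    gts = [_as_set(r) for r in gt_regions]
    pairs = []
    for gi, gt in enumerate(gts):
        for pi, pred in enumerate(preds):
            score = ioo(pred, gt)
            if score >= ioo_threshold:
                pairs.append((gi, pi, score))
    pairs.sort(key=lambda t: (-t[2], len(preds[t[1]]), t[1], t[0]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matches = []
    for gi, pi, score in pairs:
        if gi in used_gt or pi in used_pred:
            continue
        used_gt.add(gi)
        used_pred.add(pi)
        matches.append((gi, pi, score))
    tp = len(matches)
    fn = len(gts) - tp
    fp = len(preds) - tp
    return tp, fp, fn, matches


def pixel_confusion(pred_mask: np.ndarray, gt_mask: np.ndarray,
                    roi: Optional[np.ndarray] = None) -> EvalReport:
    """Pixel-level TP/FP/TN/FN within ``roi`` and the derived SE/SP/ACC."""
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    if roi is None:
        roi = np.ones(pred.shape, dtype=bool)
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != pred.shape:
            raise ValueError("roi shape differs from mask shape")
    if not roi.any():
        raise ValueError("empty region of interest")
    pred = pred[roi]
    gt = gt[roi]
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn)
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, se=se, sp=sp, acc=acc)


def evaluate_masks(pred_mask: np.ndarray, gt_mask: np.ndarray,
                   roi: Optional[np.ndarray] = None,
                   ioo_threshold: float = 0.8) -> EvalReport:
    """Full per-image report: pixel confusion plus region-level matching.

    ``per_region_ioo`` holds, for every ground-truth region, the best IOO it
    achieves against any predicted region (0 when there is no prediction);
    ``mean_ioo`` is the mean of those values.
    """
    report = pixel_confusion(pred_mask, gt_mask, roi)
    preds = regions_from_mask(pred_mask)
    gts = regions_from_mask(gt_mask)
    tp, fp, fn, _ = match_regions(preds, gts, ioo_threshold) if gts or preds \
        else (0, 0, 0, [])
    report.region_tp, report.region_fp, report.region_fn = tp, fp, fn
    per_region = []
    for gt in gts:
        best = max((ioo(pred, gt) for pred in preds), default=0.0)
        per_region.append(best)
    report.per_region_ioo = per_region
    report.mean_ioo = float(np.mean(per_region)) if per_region else float("nan")
    return report
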