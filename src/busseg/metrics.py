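"""Segmentation quality metrics.

Distances are nearest-point contour distances (mean and population standard
deviation); overlaps are measured as IoU and as ground-truth-normalized
TP/FP/FN fractions:

    TP = |A & B| / |B|,   FP = |A | B  -  B| / |B|,   FN = 1 - TP,

so TP + FN = 1 by construction and FP may exceed 1 when the prediction
spills far outside the truth.  Precision, recall and F1 are computed from
these fractions.  Because ultrasound echoes below a lesion are unreliable
(posterior shadowing), evaluation can be restricted to the upper hemisphere
of the lesion — the half of the boundary facing the transducer.

The conventional pixel-count confusion matrix is also exposed under
distinct names (:func:`pixel_confusion`) for users expecting the standard
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, InvalidInputError


@dataclass
class MetricsReport:
    """All per-frame metrics in one record."""

    d_mean: float
    d_std: float
    iou: float
    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def contour_distance(candidate, reference) -> tuple[float, float]:
    """Directed nearest-point distance statistics, candidate -> reference.

    For each candidate point the Euclidean distance to its nearest
    reference point is taken; returns the mean and the population
    (divide-by-N) standard deviation of those distances.
    """
    cand = np.atleast_2d(np.asarray(candidate, dtype=np.float64))
    ref = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    if cand.size == 0 or ref.size == 0:
        raise InvalidInputError("contours must be non-empty")
    d, _ = cKDTree(ref).query(cand)
    return float(d.mean()), float(d.std())


def _as_bool_masks(mask_a, mask_b):
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def iou(mask_a, mask_b) -> float:
    """Intersection over union; 0 when both masks are empty (convention)."""
    a, b = _as_bool_masks(mask_a, mask_b)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def overlap_fractions(mask_a, mask_b) -> tuple[float, float, float]:
    """Ground-truth-normalized (tp, fp, fn) for prediction A vs truth B.

    All three are normalized by the truth area |B|; fp can exceed 1.
    """
    a, b = _as_bool_masks(mask_a, mask_b)
    nb = np.count_nonzero(b)
    if nb == 0:
        raise InvalidInputError("ground-truth mask must be non-empty")
    tp = np.count_nonzero(a & b) / nb
    fp = np.count_nonzero(a & ~b) / nb
    return tp, fp, 1.0 - tp


def precision_recall_f1(tp: float, fp: float, fn: float):
    """Precision, recall and F1 from (possibly normalized) counts.

    Any 0/0 ratio is reported as 0 and the returned ``degenerate`` flag is
    set.  Returns ``(precision, recall, f1, degenerate)``.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise InvalidInputError("tp, fp, fn must be non-negative")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, degenerate


def pixel_confusion(mask_a, mask_b) -> dict:
    """Standard pixel-count confusion entries (not truth-normalized)."""
    a, b = _as_bool_masks(mask_a, mask_b)
    return {
        "tp_pixels": int(np.count_nonzero(a & b)),
        "fp_pixels": int(np.count_nonzero(a & ~b)),
        "fn_pixels": int(np.count_nonzero(~a & b)),
        "tn_pixels": int(np.count_nonzero(~a & ~b)),
    }


def upper_hemisphere(contour, center):
    """Keep contour points on the transducer side of the lesion center.

    Retains points whose row (y) coordinate is <= the center's row (row 0
    is the transducer surface).  Raises
    :class:`DegenerateGeometryError` when nothing remains.
    """
    pts = np.atleast_2d(np.asarray(contour, dtype=np.float64))
    if pts.size == 0:
        raise InvalidInputError("contour must be non-empty")
    kept = pts[pts[:, 1] <= float(center[1])]
    if kept.size == 0:
        raise DegenerateGeometryError("no contour points above the center")
    return kept


def hemisphere_mask(mask, center) -> np.ndarray:
    """Zero out mask rows below the center row (upper-hemisphere clipping)."""
    mask = np.asarray(mask, dtype=bool).copy()
    row = int(np.floor(float(center[1])))
    mask[row + 1:, :] = False
    return mask


def manual_variability(contours) -> tuple[float, float]:
    """Variability of repeated manual tracings of one contour.

    Pools the nearest-point distances of every unordered pair of contours
    in both directions (A->B and B->A) and returns the pooled mean and
    population standard deviation.
    """
    contours = [np.atleast_2d(np.asarray(c, dtype=np.float64)) for c in contours]
    if len(contours) < 2:
        raise InvalidInputError("need at least two contours")
    pooled = []
    for i in range(len(contours)):
        for j in range(i + 1, len(contours)):
            a, b = contours[i], contours[j]
            pooled.append(cKDTree(b).query(a)[0])
            pooled.append(cKDTree(a).query(b)[0])
    d = np.concatenate(pooled)
    return float(d.mean()), float(d.std())


def evaluate_masks(pred_mask, truth_mask, *, pred_contour=None,
                   truth_contour=None, hemisphere: bool = False,
                   center=None) -> MetricsReport:
    """Full metric report for one predicted/truth mask pair.

    Contours default to the mask boundaries.  With ``hemisphere=True`` both
    masks and contours are clipped to the upper hemisphere around
    ``center`` (defaults to the truth-mask centroid) before any metric is
    computed.
    """
    from skimage import measure

    pred, truth = _as_bool_masks(pred_mask, truth_mask)

    def boundary(mask):
        padded = np.pad(mask, 1)
        cs = measure.find_contours(padded.astype(float), 0.5)
        if not cs:
            raise InvalidInputError("cannot trace contour of an empty mask")
        rc = max(cs, key=len)[:-1] - 1.0
        return rc[:, ::-1]  # (x, y)

    if pred_contour is None:
        pred_contour = boundary(pred)
    if truth_contour is None:
        truth_contour = boundary(truth)
    if hemisphere:
        if center is None:
            rows, cols = np.nonzero(truth)
            center = (cols.mean(), rows.mean())
        pred = hemisphere_mask(pred, center)
        truth = hemisphere_mask(truth, center)
        pred_contour = upper_hemisphere(pred_contour, center)
        truth_contour = upper_hemisphere(truth_contour, center)
    d_mean, d_std = contour_distance(pred_contour, truth_contour)
    tp, fp, fn = overlap_fractions(pred, truth)
    precision, recall, f1, degenerate = precision_recall_f1(tp, fp, fn)
    return MetricsReport(d_mean=d_mean, d_std=d_std, iou=iou(pred, truth),
                         tp=tp, fp=fp, fn=fn, precision=precision,
                         recall=recall, f1=f1, degenerate=degenerate)
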