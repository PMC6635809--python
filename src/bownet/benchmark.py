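"""Contour-detection and figure-ground scoring against boundary annotations.

Implements the standard boundary-benchmark protocol: predicted boundary
maps are thinned by non-maximum suppression, thresholded at a sweep of
levels, matched one-to-one to ground-truth boundary pixels within a
distance tolerance, and summarized as precision/recall F-scores — the best
F at a single dataset-wide threshold (ODS), the mean of per-image best F
(OIS), and the area under the precision-recall curve (AP).  Figure-ground
assignment is scored as the fraction of labeled boundary points whose
predicted figure direction falls within +-90 degrees of the ground truth.

The matcher is a greedy nearest-neighbor one-to-one assignment within the
tolerance — a documented approximation of the benchmark's bipartite
assignment solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .decode import FigureGroundField, angular_difference

__all__ = [
    "PRCurve",
    "nms_thin",
    "boundary_match",
    "pr_sweep",
    "fg_accuracy",
    "default_tolerance",
]


@dataclass
class PRCurve:
    """Precision/recall sweep summaries."""

    thresholds: np.ndarray  # descending
    precision: np.ndarray
    recall: np.ndarray
    f: np.ndarray
    best_f: float  # ODS: best F at one dataset-wide threshold
    ois_f: float  # mean over images of the per-image best F
    ap: float  # area under the precision-recall curve


def default_tolerance(shape: tuple[int, int], fraction: float = 0.0075) -> float:
    """Match tolerance as a fraction of the image diagonal (benchmark default)."""
    return fraction * float(np.hypot(*shape))


def _f_score(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    denom = p + r
    return np.where(denom > 0, 2.0 * p * r / np.where(denom > 0, denom, 1.0), 0.0)


def nms_thin(field: FigureGroundField) -> np.ndarray:
    """Thin a BOS magnitude map along the local figure-direction normal.

    The decoded angle points across the contour (toward the figure), so a
    pixel survives when its magnitude is not exceeded by the bilinearly
    interpolated magnitudes one pixel away on either side along that
    direction.
    """
    m, a = field.magnitude, field.angle
    h, w = m.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = -np.sin(a), np.cos(a)  # array-coordinate step along the angle
    ahead = ndimage.map_coordinates(m, [rr + dr, cc + dc], order=1, mode="constant")
    behind = ndimage.map_coordinates(m, [rr - dr, cc - dc], order=1, mode="constant")
    keep = (m >= ahead) & (m >= behind)
    return np.where(keep, m, 0.0)


def boundary_match(
    pred: np.ndarray, true: np.ndarray, tolerance: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of boundary pixel sets within a tolerance.

    Parameters are (N, 2) and (M, 2) integer coordinate arrays.  Returns
    ``(n_matched, n_pred_unmatched, n_true_unmatched)``; unmatched
    predictions count against precision, unmatched truths against recall.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    true = np.atleast_2d(np.asarray(true, dtype=float))
    n_pred = 0 if pred.size == 0 else pred.shape[0]
    n_true = 0 if true.size == 0 else true.shape[0]
    if n_pred == 0 or n_true == 0:
        return 0, n_pred, n_true
    dist = cKDTree(pred).sparse_distance_matrix(
        cKDTree(true), max_distance=tolerance, output_type="coo_matrix"
    )
    order = np.argsort(dist.data, kind="stable")
    used_p = np.zeros(n_pred, dtype=bool)
    used_t = np.zeros(n_true, dtype=bool)
    matched = 0
    for i, j in zip(dist.row[order], dist.col[order]):
        if not used_p[i] and not used_t[j]:
            used_p[i] = used_t[j] = True
            matched += 1
    return matched, n_pred - matched, n_true - matched


def pr_sweep(
    fields: FigureGroundField | list[FigureGroundField],
    truths: np.ndarray | list[np.ndarray],
    n_thresholds: int = 99,
    tolerance: float | None = None,
    thin: bool = True,
) -> PRCurve:
    """Threshold sweep of BOS magnitude against true boundary masks.

    Accepts a single image or a dataset (lists of fields and masks).
    Magnitudes are normalized to [0, 1] per image and optionally thinned
    before thresholding.  Aggregated counts across images give the ODS
    curve; per-image best F-scores give OIS; AP integrates precision over
    recall.
    """
    if isinstance(fields, FigureGroundField):
        fields, truths = [fields], [truths]
    if len(fields) != len(truths):
        raise ValueError("need one truth mask per field")
    thresholds = np.linspace(n_thresholds, 1, n_thresholds) / (n_thresholds + 1)

    tp = np.zeros((len(fields), n_thresholds))
    npred = np.zeros_like(tp)
    ntrue = np.zeros(len(fields))
    for i, (field, mask) in enumerate(zip(fields, truths)):
        tol = default_tolerance(mask.shape) if tolerance is None else tolerance
        mag = nms_thin(field) if thin else field.magnitude.copy()
        peak = mag.max()
        if peak > 0:
            mag = mag / peak
        true_coords = np.argwhere(mask)
        ntrue[i] = len(true_coords)
        for t, thr in enumerate(thresholds):
            pred_coords = np.argwhere(mag >= thr)
            m, _, _ = boundary_match(pred_coords, true_coords, tol)
            tp[i, t] = m
            npred[i, t] = len(pred_coords)

    def curve(tp_t, npred_t, ntrue_tot):
        p = np.where(npred_t > 0, tp_t / np.where(npred_t > 0, npred_t, 1), 0.0)
        r = tp_t / ntrue_tot if ntrue_tot > 0 else np.zeros_like(tp_t)
        return p, r, _f_score(p, r)

    p, r, f = curve(tp.sum(0), npred.sum(0), ntrue.sum())
    per_image_best = [
        curve(tp[i], npred[i], ntrue[i])[2].max() for i in range(len(fields))
    ]
    order = np.argsort(r, kind="stable")
    ap = float(np.trapezoid(p[order], r[order]))
    return PRCurve(
        thresholds=thresholds,
        precision=p,
        recall=r,
        f=f,
        best_f=float(f.max()),
        ois_f=float(np.mean(per_image_best)),
        ap=ap,
    )


def fg_accuracy(pred_angles: np.ndarray, true_angles: np.ndarray) -> float:
    """Fraction of points whose predicted figure direction is within +-90 deg.

    The comparison is strict: a prediction exactly 90 degrees off counts as
    incorrect.
    """
    pred_angles = np.asarray(pred_angles, dtype=float)
    true_angles = np.asarray(true_angles, dtype=float)
    if pred_angles.size == 0:
        raise ValueError("fg_accuracy of an empty point list is undefined")
    if pred_angles.shape != true_angles.shape:
        raise ValueError("predicted and true angle lists must be co-located")
    return float(np.mean(angular_difference(pred_angles, true_angles) < np.pi / 2.0))
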