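"""Segmentation quality: Jaccard index, Jaccard curves and operating points.

The Jaccard index JAC = TP / (TP + FP + FN) is the intersection over union
of the predicted and ground-truth positive regions, computed one-vs-rest per
positive class.  Because a single Jaccard depends on the classification
threshold, the *Jaccard curve* sweeps the threshold over the sorted voxel
scores and plots Jaccard against the fraction of voxels labeled background;
higher curves mean better segmentations at every operating point.  Two
named operating points are supported: the zero score threshold that boosting
classifiers deploy (the sign rule), and the maximum-a-posteriori rule of
probabilistic classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from emseg.piboost import posterior


@dataclass
class ConfusionCounts:
    """Voxel-level confusion counts for one positive class vs the rest."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class JaccardCurve:
    """(background_fraction, jaccard) points plus named operating points."""

    points: np.ndarray                       # (n_points, 2)
    operating_points: dict[str, tuple[float, float]]


def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def jaccard(pred: np.ndarray, gt: np.ndarray) -> float:
    """JAC = TP / (TP + FP + FN), in [0, 1].

    Two empty masks score 1 (degenerate perfection); exactly one empty mask
    scores 0.
    """
    c = confusion(pred, gt)
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def jaccard_curve(scores: np.ndarray, gt: np.ndarray, n_points: int = 200
                  ) -> JaccardCurve:
    """Sweep thresholds over the sorted scores and record the Jaccard.

    ``scores`` is the positive-class score per voxel (for the multi-class
    boosting model, the class's component of f).  Thresholds sit at rank
    quantiles of the scores; a voxel is positive when its score is greater
    than or equal to the threshold, so the x-coordinate is the fraction of
    voxels strictly below it (the fraction labeled background).
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    g = np.asarray(gt, dtype=bool).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite values")
    if s.size != g.size:
        raise ValueError("scores and ground truth differ in size")
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    ranks = np.unique(np.linspace(0, s.size - 1, n_points).round().astype(int))
    pts = np.empty((ranks.size, 2))
    for i, r in enumerate(ranks):
        thr = s_sorted[r]
        pred = s >= thr
        pts[i, 0] = np.count_nonzero(s < thr) / s.size
        pts[i, 1] = jaccard(pred, g)
    return JaccardCurve(pts, {})


def operating_point(scores: np.ndarray, gt: np.ndarray, class_index: int,
                    kind: str = "zero_threshold") -> tuple[float, float]:
    """Place a named operating point: (background_fraction, jaccard).

    ``scores`` is the full (voxels x classes) score array f.  The
    ``zero_threshold`` point labels a voxel positive when its class score is
    strictly greater than zero (boosting's sign rule); ``map`` labels it
    positive when the class attains the maximum posterior (ties resolve to
    the lowest class index).
    """
    f = np.asarray(scores, dtype=np.float64)
    g = np.asarray(gt, dtype=bool)
    flat = f.reshape(-1, f.shape[-1])
    if kind == "zero_threshold":
        mask = flat[:, class_index] > 0.0
    elif kind == "map":
        p = posterior(flat)
        mask = np.argmax(p, axis=-1) == class_index
    else:
        raise ValueError(f"unknown operating point kind {kind!r}")
    bg_fraction = 1.0 - np.count_nonzero(mask) / mask.size
    return float(bg_fraction), jaccard(mask.reshape(g.shape), g)
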