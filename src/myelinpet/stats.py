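"""Discrimination statistics and tidy per-ROI export.

ROC analysis asks how well a voxelwise quantity (DVR, SUV) separates
demyelinated lesion tissue from normal-appearing white matter. Because a
demyelinated voxel binds *less* tracer, the lesion class sits at the low end
of the score scale; orientation is configurable and recorded. The AUC is the
trapezoidal area of the empirical ROC curve, identical to the Mann-Whitney
concordance probability with half credit for ties. Two AUCs measured on the
same voxels are compared with the DeLong test for correlated ROC curves
(implemented here from midranks; no pre-installed package provides it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .core import ParametricMap
from .geometry import LayerSet
from .logan import roi_mean

__all__ = ["RocResult", "roc_auc", "compare_auc", "export_roi_table", "layerset_rois"]


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    variance: float  # DeLong variance of the AUC estimate
    fpr: np.ndarray
    tpr: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n, float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, float)
    out[order] = ranks
    return out


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUCs and DeLong covariance for k score sets on one paired sample.

    ``scores`` is (k, n); ``labels`` boolean with True = positive class
    (the class expected to have the *higher* decision values).
    """
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01[0], ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10[0], ddof=1))
    cov = s01 / m + s10 / n
    return aucs, np.atleast_2d(cov)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, positive_is_low: bool = True
) -> RocResult:
    """ROC curve and AUC for a binary lesion-vs-NAWM labelling.

    ``labels`` True marks the positive (lesion) class. With
    ``positive_is_low`` (the default for binding measures, where lesions
    score low) the decision value is the negated score, so AUC is the
    probability a random lesion voxel scores below a random NAWM voxel.
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels, bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    decision = -scores if positive_is_low else scores
    fpr, tpr, _ = _roc_curve(labels, decision)
    area = float(_trapezoid_auc(fpr, tpr))
    aucs, cov = _delong_components(decision[None, :], labels)
    return RocResult(
        auc=area,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        variance=float(cov[0, 0]),
        fpr=fpr,
        tpr=tpr,
        provenance={"positive_is_low": positive_is_low},
    )


def compare_auc(
    scores1: np.ndarray,
    scores2: np.ndarray,
    labels: np.ndarray,
    positive_is_low: bool = True,
) -> tuple[float, float, float]:
    """DeLong test for two correlated AUCs measured on the same voxels.

    Returns (AUC1 - AUC2, z statistic, two-sided p). The two score vectors
    must be paired sample-for-sample with one label vector.
    """
    s1 = np.asarray(scores1, float).ravel()
    s2 = np.asarray(scores2, float).ravel()
    labels = np.asarray(labels, bool).ravel()
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValueError("scores1, scores2 and labels must be paired (equal length)")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    sign = -1.0 if positive_is_low else 1.0
    aucs, cov = _delong_components(sign * np.vstack([s1, s2]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        return delta, 0.0, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return delta, float(z), p


def layerset_rois(layers: LayerSet, extra: dict[str, np.ndarray] | None = None) -> dict[str, np.ndarray]:
    """Flatten a LayerSet (plus optional extra masks, e.g. NAWM) into named ROIs."""
    rois: dict[str, np.ndarray] = dict(extra or {})
    for k in layers.lesion_ids:
        rois[f"lesion{k}_core"] = layers.core(k)
        for i, m in enumerate(layers.intralesional.get(k, [])):
            rois[f"lesion{k}_intralesional_{i + 1}"] = m
        for (lo, hi), m in zip(layers.bounds_mm, layers.perilesional.get(k, [])):
            rois[f"lesion{k}_perilesional_{lo:g}_{hi:g}mm"] = m
    return rois


def export_roi_table(
    maps: list[ParametricMap],
    rois: dict[str, np.ndarray],
    subject_meta: dict[str, Any] | None = None,
) -> pd.DataFrame:
    """One tidy row per ROI x quantity: mean, SD, voxel count, volume.

    This is the hand-off point to off-the-shelf group statistics (mixed
    models etc.), which operate on the exported table rather than on images.
    Empty ROIs are skipped with a warning.
    """
    meta = subject_meta or {}
    rows = []
    for pmap in maps:
        vol = float(np.prod(pmap.voxel_size_mm))
        for name, mask in rois.items():
            mask = np.asarray(mask, bool)
            if mask.shape != pmap.values.shape:
                raise ValueError(f"ROI {name!r} grid does not match the {pmap.quantity} map")
            finite = np.isfinite(pmap.values) & mask
            if not finite.any():
                warnings.warn(f"ROI {name!r} is empty for {pmap.quantity}; row omitted", stacklevel=2)
                continue
            mean, sd, n = roi_mean(pmap, mask)
            rows.append(
                {**meta, "roi": name, "quantity": pmap.quantity, "units": pmap.units,
                 "mean": mean, "sd": sd, "n_voxels": n, "volume_mm3": n * vol}
            )
    return pd.DataFrame(rows)
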