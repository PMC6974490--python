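"""Voxelwise Logan graphical reference analysis producing DVR maps.

After an equilibration time t*, the transformed coordinates

    Y(t) = int_0^t C_t dtau / C_t(t)
    X(t) = [ int_0^t C_ref dtau  (+ C_ref(t)/k2' when k2' is given) ] / C_t(t)

become linear and the slope of Y on X is the distribution volume ratio
(DVR). Integrals are evaluated by the trapezoidal rule on the frame
midpoints with a C(0) = 0 anchor; the fit is ordinary least squares on the
frames whose midpoints are at or after t*. The k2' term is omitted by
default and exposed as an optional argument.
"""

from __future__ import annotations

import numpy as np

from .core import DynamicImage, ParametricMap

__all__ = ["logan_dvr", "roi_mean", "cumulative_integral"]


def cumulative_integral(curves: np.ndarray, mid_min: np.ndarray) -> np.ndarray:
    """Trapezoidal running integral along the last axis, anchored at C(0)=0.

    ``curves`` has frames on its last axis sampled at ``mid_min`` (minutes);
    the integral at frame i covers [0, mid_min[i]].
    """
    t = np.concatenate([[0.0], mid_min])
    c = np.concatenate([np.zeros(curves.shape[:-1] + (1,)), curves], axis=-1)
    seg = 0.5 * np.diff(t) * (c[..., 1:] + c[..., :-1])
    return np.cumsum(seg, axis=-1)


def logan_dvr(
    img: DynamicImage,
    ref_tac: np.ndarray,
    t_star_min: float = 30.0,
    k2prime: float | None = None,
    brain_mask: np.ndarray | None = None,
) -> ParametricMap:
    """Fit the Logan reference plot in every (brain) voxel; DVR = slope.

    Voxels whose late-frame activity is not strictly positive cannot be
    transformed and are flagged NaN; their count is recorded in provenance
    as ``n_invalid``.
    """
    ref_tac = np.asarray(ref_tac, float)
    if ref_tac.shape != (img.scheme.n_frames,):
        raise ValueError("reference TAC length does not match the frame scheme")
    if not img.decay_corrected:
        raise ValueError("Logan analysis expects decay-corrected frames")
    mid = img.scheme.mid_min
    fit = mid >= t_star_min
    if fit.sum() < 3:
        raise ValueError(f"need at least 3 frames with midpoint >= t* ({t_star_min} min)")
    if np.any(ref_tac[fit] <= 0):
        raise ValueError("reference TAC must be positive over the fit window")

    if brain_mask is None:
        brain_mask = np.ones(img.shape3d, bool)
    brain_mask = np.asarray(brain_mask, bool)

    ct = img.data[brain_mask]  # (n_vox, n_frames)
    int_ct = cumulative_integral(ct, mid)[:, fit]
    int_ref = cumulative_integral(ref_tac, mid)[fit]
    ct_fit = ct[:, fit]

    valid = np.all(ct_fit > 0, axis=1)
    n_invalid = int((~valid).sum())
    slope = np.full(ct.shape[0], np.nan)
    if valid.any():
        ctv = ct_fit[valid]
        y = int_ct[valid] / ctv
        x = int_ref[None, :] / ctv
        if k2prime is not None:
            x = x + ref_tac[fit][None, :] / (k2prime * ctv)
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = ((x - xm) ** 2).sum(axis=1)
        sxy = ((x - xm) * (y - ym)).sum(axis=1)
        good = sxx > 0
        s = np.full(ctv.shape[0], np.nan)
        s[good] = sxy[good] / sxx[good]
        slope[valid] = s
        n_invalid += int((~good).sum())

    out = np.full(img.shape3d, np.nan)
    out[brain_mask] = slope
    return ParametricMap(
        values=out,
        quantity="DVR",
        units="unitless",
        voxel_size_mm=img.voxel_size_mm,
        affine=img.affine,
        provenance={
            "stage": "logan.logan_dvr",
            "t_star_min": t_star_min,
            "k2prime": k2prime,
            "n_fit_frames": int(fit.sum()),
            "n_invalid": n_invalid,
            "reference": "mean TAC of supplied reference region",
        },
    )


def roi_mean(pmap: ParametricMap, roi_mask: np.ndarray) -> tuple[float, float, int]:
    """Mean, SD and voxel count of a parametric map over an ROI.

    Only finite (valid) voxels inside the ROI contribute; an ROI with no
    valid voxel is an error.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.shape != pmap.values.shape:
        raise ValueError("ROI grid does not match the map")
    vals = pmap.values[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid voxels")
    return float(vals.mean()), float(vals.std(ddof=0)), int(vals.size)
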