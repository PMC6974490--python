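"""Lesion-centric mask algebra.

Builds the region system used for lesion-layer analysis of white matter:
normal-appearing white matter (NAWM = WM minus all T1/T2 lesions),
perilesional distance rings outside each lesion (default 0-4 mm and 4-8 mm
bands, measured in-plane per axial slice as the ROIs were drawn), depth
layers inside each lesion, exclusion of lesions smaller than the scanner
resolution, and the DVR-based impaired-white-matter cutoff mask
(mean - 1.96 SD of a reference white-matter distribution).

Distances are exact Euclidean distance transforms with physical voxel
spacing; "distance from the lesion" means distance to the nearest lesion
voxel centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ParametricMap

__all__ = [
    "LayerSet",
    "nawm_mask",
    "perilesional_rings",
    "intralesional_layers",
    "filter_small_lesions",
    "impaired_wm_mask",
]

PET_RESOLUTION_MM = 4.3  # scanner point-spread FWHM used as the size cutoff


@dataclass
class LayerSet:
    """Per-lesion core, intralesional depth layers and perilesional rings.

    ``intralesional[k]`` lists masks from outer (shallow) to inner (deep);
    ``perilesional[k]`` lists one mask per distance band in ``bounds_mm``.
    """

    lesion_labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    distance_mode: str = "2d"
    bounds_mm: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 4.0), (4.0, 8.0)])
    intralesional: dict[int, list[np.ndarray]] = field(default_factory=dict)
    perilesional: dict[int, list[np.ndarray]] = field(default_factory=dict)

    @property
    def lesion_ids(self) -> list[int]:
        return sorted(int(k) for k in np.unique(self.lesion_labels) if k != 0)

    def core(self, lesion_id: int) -> np.ndarray:
        return self.lesion_labels == lesion_id

    def catalogue(self) -> pd.DataFrame:
        """Tidy per-lesion layer inventory: id, layer, voxel count, volume."""
        vol = float(np.prod(self.voxel_size_mm))
        rows = []
        for k in self.lesion_ids:
            rows.append({"lesion_id": k, "layer": "core", "n_voxels": int(self.core(k).sum())})
            for i, m in enumerate(self.intralesional.get(k, [])):
                name = f"intralesional_{i + 1}" if len(self.intralesional[k]) > 2 else (
                    "intralesional_outer" if i == 0 else "intralesional_inner"
                )
                rows.append({"lesion_id": k, "layer": name, "n_voxels": int(m.sum())})
            for (lo, hi), m in zip(self.bounds_mm, self.perilesional.get(k, [])):
                rows.append({"lesion_id": k, "layer": f"perilesional_{lo:g}_{hi:g}mm", "n_voxels": int(m.sum())})
        df = pd.DataFrame(rows)
        if len(df):
            df["volume_mm3"] = df["n_voxels"] * vol
        return df


def nawm_mask(
    wm_mask: np.ndarray, t1_lesions: np.ndarray, t2_lesions: np.ndarray
) -> np.ndarray:
    """Normal-appearing white matter: WM with the union of the T1 and T2
    lesion masks removed. Lesion voxels falling outside WM are legal input
    (registration slop in real data) but flagged with a warning."""
    wm = np.asarray(wm_mask, bool)
    lesions = (np.asarray(t1_lesions) != 0) | (np.asarray(t2_lesions) != 0)
    if wm.shape != lesions.shape:
        raise ValueError("masks must share one grid")
    outside = int((lesions & ~wm).sum())
    if outside:
        warnings.warn(f"{outside} lesion voxel(s) lie outside the white-matter mask", stacklevel=2)
    return wm & ~lesions


def _distance_outside(lesion: np.ndarray, voxel_size: tuple[float, float, float], mode: str) -> np.ndarray:
    """Distance (mm) from every voxel to the nearest lesion voxel centre.

    mode '3d': full volumetric EDT. mode '2d': computed independently per
    axial slice (last axis); slices containing no lesion voxel get +inf.
    """
    lesion = np.asarray(lesion, bool)
    if mode == "3d":
        return ndimage.distance_transform_edt(~lesion, sampling=voxel_size)
    if mode != "2d":
        raise ValueError("distance mode must be '2d' or '3d'")
    if not np.isclose(voxel_size[0], voxel_size[1]):
        raise ValueError("2D in-plane mode requires equal in-plane voxel spacing")
    out = np.full(lesion.shape, np.inf)
    for s in range(lesion.shape[2]):
        sl = lesion[:, :, s]
        if sl.any():
            out[:, :, s] = ndimage.distance_transform_edt(~sl, sampling=voxel_size[:2])
    return out


def perilesional_rings(
    lesion_labels: np.ndarray,
    wm_mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    bounds_mm: list[tuple[float, float]] | None = None,
    mode: str = "2d",
    layer_set: LayerSet | None = None,
) -> LayerSet:
    """Distance bands outside each lesion, clipped to white matter.

    For each lesion k and band (lo, hi], the ring is {voxel outside all
    lesions: lo < d_k <= hi} with d_k the distance to lesion k. Ring voxels
    claimed by more than one lesion in the same band are excluded from every
    claimant (conservative overlap handling), and no ring voxel may lie
    inside any lesion.
    """
    lesion_labels = np.asarray(lesion_labels)
    wm = np.asarray(wm_mask, bool)
    if lesion_labels.shape != wm.shape:
        raise ValueError("lesion and WM masks must share one grid")
    if not (lesion_labels != 0).any():
        raise ValueError("no lesion voxels present")
    if bounds_mm is None:
        bounds_mm = [(0.0, 4.0), (4.0, 8.0)]
    any_lesion = lesion_labels != 0
    ls = layer_set or LayerSet(
        lesion_labels=lesion_labels, voxel_size_mm=tuple(voxel_size_mm),
        distance_mode=mode, bounds_mm=list(bounds_mm),
    )
    ls.bounds_mm = list(bounds_mm)
    ls.distance_mode = mode

    ids = [int(k) for k in np.unique(lesion_labels) if k != 0]
    candidate = {k: [] for k in ids}
    for k in ids:
        d = _distance_outside(lesion_labels == k, tuple(voxel_size_mm), mode)
        for lo, hi in bounds_mm:
            ring = (d > lo) & (d <= hi) & wm & ~any_lesion
            candidate[k].append(ring)
    # conservative overlap exclusion: a voxel in two lesions' same-band rings
    # belongs to neither
    for b in range(len(bounds_mm)):
        claims = np.zeros(lesion_labels.shape, dtype=np.int16)
        for k in ids:
            claims += candidate[k][b]
        overlap = claims > 1
        for k in ids:
            candidate[k][b] = candidate[k][b] & ~overlap
    ls.perilesional = candidate
    return ls


def intralesional_layers(
    lesion_labels: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    n_layers: int = 2,
    layer_set: LayerSet | None = None,
) -> LayerSet:
    """Split each lesion into ``n_layers`` equal-depth bands.

    Depth is the 3-D distance from a lesion voxel to the nearest voxel
    outside that lesion; the depth range (0, d_max] is cut into n equal
    bins, outer (shallow) first. The bins partition the lesion exactly. A
    lesion whose voxels all share one depth (e.g. a single voxel) cannot be
    split: everything goes to the outer layer with a warning.
    """
    lesion_labels = np.asarray(lesion_labels)
    if not (lesion_labels != 0).any():
        raise ValueError("no lesion voxels present")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    ls = layer_set or LayerSet(lesion_labels=lesion_labels, voxel_size_mm=tuple(voxel_size_mm))
    result: dict[int, list[np.ndarray]] = {}
    for k in (int(v) for v in np.unique(lesion_labels) if v != 0):
        core = lesion_labels == k
        depth = ndimage.distance_transform_edt(core, sampling=voxel_size_mm)
        d = depth[core]
        layers = [np.zeros(core.shape, bool) for _ in range(n_layers)]
        if n_layers == 1:
            layers[0] = core.copy()
        elif np.unique(d).size < 2:
            warnings.warn(f"lesion {k} too small to split into {n_layers} layers; all voxels to outer layer", stacklevel=2)
            layers[0] = core.copy()
        else:
            dmax = d.max()
            # bin i (0-based, outer first): depth in (i*dmax/n, (i+1)*dmax/n]
            bins = np.minimum(np.ceil(d / (dmax / n_layers)).astype(int) - 1, n_layers - 1)
            bins = np.maximum(bins, 0)
            coords = np.argwhere(core)
            for i in range(n_layers):
                sel = coords[bins == i]
                layers[i][tuple(sel.T)] = True
        result[k] = layers
    ls.intralesional = result
    return ls


def filter_small_lesions(
    lesion_labels: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    min_diameter_mm: float = PET_RESOLUTION_MM,
) -> tuple[np.ndarray, dict[str, int]]:
    """Drop lesions smaller than the scanner resolution.

    Size is the equivalent-sphere diameter of the component volume,
    d = (6 V / pi)^(1/3); components with d < ``min_diameter_mm`` are
    removed (labels of retained lesions are preserved). Returns the filtered
    label map and a {'retained': n, 'dropped': m} report.
    """
    lesion_labels = np.asarray(lesion_labels)
    vol = float(np.prod(voxel_size_mm))
    out = lesion_labels.copy()
    retained = dropped = 0
    for k in (int(v) for v in np.unique(lesion_labels) if v != 0):
        n = int((lesion_labels == k).sum())
        d_eq = (6.0 * n * vol / np.pi) ** (1.0 / 3.0)
        if d_eq < min_diameter_mm:
            out[out == k] = 0
            dropped += 1
        else:
            retained += 1
    return out, {"retained": retained, "dropped": dropped}


def impaired_wm_mask(
    dvr: ParametricMap | np.ndarray,
    wm_mask: np.ndarray,
    ref_mean: float,
    ref_sd: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold white matter into myelin-impaired vs unaffected tissue.

    The cutoff is ref_mean - 1.96 * ref_sd, the lower tail of a reference
    (healthy white matter) DVR distribution; WM voxels with DVR strictly
    below it are 'impaired', the rest (including voxels with no valid DVR)
    'unaffected'. The two masks partition WM.
    """
    if ref_sd <= 0:
        raise ValueError("reference SD must be positive")
    values = dvr.values if isinstance(dvr, ParametricMap) else np.asarray(dvr, float)
    wm = np.asarray(wm_mask, bool)
    if values.shape != wm.shape:
        raise ValueError("DVR map and WM mask must share one grid")
    cutoff = float(ref_mean - 1.96 * ref_sd)
    with np.errstate(invalid="ignore"):
        impaired = wm & (values < cutoff)
    unaffected = wm & ~impaired
    return impaired, unaffected, cutoff
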