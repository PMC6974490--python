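"""Standardized uptake value (SUV) and SUV-ratio maps.

SUV = C / (ID / BW) with the activity concentration C in kBq/ml, injected
dose ID in MBq and body weight BW in kg. With the implicit 1 g/ml tissue
density this is the usual body-weight-normalized uptake (the kBq/ml vs
MBq/kg unit pair cancels numerically). The late static image feeding this
map is produced by :func:`myelinpet.framing.window_average` on
decay-corrected frames — conventionally the 70-90 min window.
"""

from __future__ import annotations

import numpy as np

from .core import ParametricMap

__all__ = ["suv_map", "suvr_map"]


def suv_map(
    static: np.ndarray,
    injected_dose_MBq: float,
    body_weight_kg: float,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    window_min: tuple[float, float] | None = None,
) -> ParametricMap:
    """Voxelwise SUV from a static activity map (kBq/ml)."""
    if injected_dose_MBq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected dose and body weight must be positive")
    static = np.asarray(static, float)
    values = static / (injected_dose_MBq / body_weight_kg)
    return ParametricMap(
        values=values,
        quantity="SUV",
        units="unitless (g/ml density convention)",
        voxel_size_mm=voxel_size_mm,
        provenance={
            "stage": "suv.suv_map",
            "injected_dose_MBq": injected_dose_MBq,
            "body_weight_kg": body_weight_kg,
            "window_min": list(window_min) if window_min else None,
        },
    )


def suvr_map(suv: ParametricMap, ref_mask: np.ndarray) -> ParametricMap:
    """SUV ratio to the mean SUV of a reference mask.

    Provided for completeness: an SUVR is only meaningful when the reference
    region's uptake is comparable across the groups being contrasted, which
    must be verified first — the provenance carries a warning to that effect.
    """
    ref_mask = np.asarray(ref_mask, bool)
    if ref_mask.shape != suv.values.shape:
        raise ValueError("reference mask grid does not match the SUV map")
    if not ref_mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(suv.values[ref_mask].mean())
    if ref_mean <= 0:
        raise ValueError("reference-region mean SUV must be positive")
    return ParametricMap(
        values=suv.values / ref_mean,
        quantity="SUVR",
        units="unitless",
        voxel_size_mm=suv.voxel_size_mm,
        affine=suv.affine,
        provenance={
            "stage": "suv.suvr_map",
            "reference_mean_suv": ref_mean,
            "n_reference_voxels": int(ref_mask.sum()),
            "warning": "SUVR is valid only if reference uptake does not differ between groups",
            "parent": suv.provenance,
        },
    )
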