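"""Supervised cluster analysis (SVCA) reference-region extraction.

The reference region for reference-tissue kinetic modelling is found without
anatomy: every voxel's time-activity curve is z-scored frame by frame over
the brain, three kinetic classes (normal grey matter, blood pool, white
matter) are built from control scans, each candidate voxel's normalized TAC
is regressed on the classes with non-negative least squares, and voxels
whose class-1 (grey matter) weight ratio exceeds 0.9 form the reference
region. The reference TAC is the mean of the *raw* (non-normalized) curves
in that region.

Class construction follows the three-class recipe: classes 1 and 3 are grand
means of normalized grey-/white-matter TACs over the control scans; class 2
is the mean normalized TAC of, per control scan, the 30 voxels with the
highest summed raw activity over the frames wholly inside the first 60 s
(the large blood vessels). Selection happens per scan and is then averaged;
rank ties at the cutoff are broken by lexicographic voxel index so the
extraction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import nnls

from .core import DynamicImage

__all__ = [
    "KineticClassSet",
    "ReferenceRegion",
    "normalize_frames",
    "select_blood_voxels",
    "build_classes",
    "extract_reference",
]

IGNORE_VALUE = np.nan  # normalized value outside the brain mask


@dataclass
class KineticClassSet:
    """The three normalized kinetic class curves used by SVCA."""

    class1_gm: np.ndarray
    class2_blood: np.ndarray
    class3_wm: np.ndarray
    n_controls: int = 1

    def __post_init__(self) -> None:
        c1, c2, c3 = (np.asarray(c, float) for c in (self.class1_gm, self.class2_blood, self.class3_wm))
        if not (c1.shape == c2.shape == c3.shape) or c1.ndim != 1:
            raise ValueError("class TACs must be 1-D and share one frame scheme")
        for a, b, names in ((c1, c2, "1/2"), (c1, c3, "1/3"), (c2, c3, "2/3")):
            if np.allclose(a, b):
                raise ValueError(f"kinetic classes {names} are identical; classes must be distinct")
        self.class1_gm, self.class2_blood, self.class3_wm = c1, c2, c3

    @property
    def n_frames(self) -> int:
        return int(self.class1_gm.size)

    def as_matrix(self) -> np.ndarray:
        """(n_frames, 3) design matrix, class 1 first."""
        return np.column_stack([self.class1_gm, self.class2_blood, self.class3_wm])

    def to_dict(self) -> dict[str, Any]:
        return {
            "class1_gm": self.class1_gm.tolist(),
            "class2_blood": self.class2_blood.tolist(),
            "class3_wm": self.class3_wm.tolist(),
            "n_controls": self.n_controls,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticClassSet":
        return cls(
            np.asarray(d["class1_gm"], float),
            np.asarray(d["class2_blood"], float),
            np.asarray(d["class3_wm"], float),
            int(d.get("n_controls", 1)),
        )


@dataclass
class ReferenceRegion:
    mask: np.ndarray
    ref_tac: np.ndarray
    weight_map: np.ndarray  # class-1 weight ratio per voxel (nan outside search mask)
    threshold: float = 0.9
    provenance: dict[str, Any] = field(default_factory=dict)


def normalize_frames(img: DynamicImage, brain_mask: np.ndarray) -> np.ndarray:
    """Frame-wise z-scoring over the brain.

    For each frame the brain-voxel mean is subtracted and the result divided
    by the brain-voxel SD, putting every frame on a common scale regardless
    of global activity; voxels outside the brain are set to NaN.
    """
    brain_mask = np.asarray(brain_mask, bool)
    if brain_mask.shape != img.shape3d:
        raise ValueError("brain mask grid does not match the image")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    vals = img.data[brain_mask]  # (n_brain, n_frames)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise ValueError(f"frame(s) {zero_var.tolist()} have zero variance over the brain; cannot normalize")
    out = np.full(img.data.shape, IGNORE_VALUE)
    out[brain_mask] = (vals - mean) / sd
    return out


def _early_frame_selector(img: DynamicImage, early_window_s: float) -> np.ndarray:
    sel = img.scheme.end_s <= early_window_s
    if not sel.any():
        raise ValueError(f"no frame lies wholly within the first {early_window_s:g} s")
    return sel


def select_blood_voxels(
    img: DynamicImage, brain_mask: np.ndarray, n_voxels: int = 30, early_window_s: float = 60.0
) -> np.ndarray:
    """Flat brain-voxel indices of the ``n_voxels`` highest summed raw
    activities over frames wholly inside the early window (blood pool).

    Ties at the cutoff rank are broken by lexicographic (C-order) voxel
    index: among equal scores the smaller flat index wins.
    """
    brain_mask = np.asarray(brain_mask, bool)
    flat_idx = np.flatnonzero(brain_mask.ravel())
    if flat_idx.size < n_voxels:
        raise ValueError(f"brain mask has {flat_idx.size} voxels; need at least {n_voxels}")
    sel = _early_frame_selector(img, early_window_s)
    score = img.data.reshape(-1, img.scheme.n_frames)[flat_idx][:, sel].sum(axis=1)
    # stable sort on (-score, index): lexicographic tie-break, deterministic
    order = np.lexsort((flat_idx, -score))
    return flat_idx[order[:n_voxels]]


def build_classes(
    control_imgs: list[DynamicImage],
    gm_masks: list[np.ndarray],
    wm_masks: list[np.ndarray],
    brain_masks: list[np.ndarray] | None = None,
    n_blood_voxels: int = 30,
    early_window_s: float = 60.0,
) -> KineticClassSet:
    """Average normalized control-scan kinetics into the three SVCA classes."""
    if not control_imgs:
        raise ValueError("at least one control scan is required")
    if not (len(control_imgs) == len(gm_masks) == len(wm_masks)):
        raise ValueError("one GM and one WM mask per control scan required")
    if brain_masks is None:
        brain_masks = [np.asarray(g, bool) | np.asarray(w, bool) for g, w in zip(gm_masks, wm_masks)]
    c1, c2, c3 = [], [], []
    for img, gm, wm, brain in zip(control_imgs, gm_masks, wm_masks, brain_masks):
        gm, wm, brain = (np.asarray(m, bool) for m in (gm, wm, brain))
        if not gm.any() or not wm.any():
            raise ValueError("GM and WM masks must be nonempty")
        z = normalize_frames(img, brain)
        c1.append(z[gm].mean(axis=0))
        c3.append(z[wm].mean(axis=0))
        blood_idx = select_blood_voxels(img, brain, n_blood_voxels, early_window_s)
        c2.append(z.reshape(-1, img.scheme.n_frames)[blood_idx].mean(axis=0))
    return KineticClassSet(
        class1_gm=np.mean(c1, axis=0),
        class2_blood=np.mean(c2, axis=0),
        class3_wm=np.mean(c3, axis=0),
        n_controls=len(control_imgs),
    )


def extract_reference(
    img: DynamicImage,
    classes: KineticClassSet,
    search_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    threshold: float = 0.9,
    solver: str = "nnls",
) -> ReferenceRegion:
    """Select reference voxels by class-1 weight ratio and average their raw TACs.

    Each search-mask voxel's normalized TAC is modelled as a non-negative
    linear combination of the three classes; the class-1 weight ratio
    w1 / (w1 + w2 + w3) must exceed ``threshold`` for selection (ratio
    defined as 0 when all weights vanish). ``solver='ols'`` fits by ordinary
    least squares instead, with the same ratio definition on the raw
    coefficients.
    """
    search_mask = np.asarray(search_mask, bool)
    if search_mask.shape != img.shape3d:
        raise ValueError("search mask grid does not match the image")
    if not search_mask.any():
        raise ValueError("search mask is empty")
    if classes.n_frames != img.scheme.n_frames:
        raise ValueError("kinetic classes are defined on a different frame scheme")
    if brain_mask is None:
        brain_mask = search_mask
    z = normalize_frames(img, np.asarray(brain_mask, bool) | search_mask)

    design = classes.as_matrix()
    coords = np.argwhere(search_mask)
    ratios = np.zeros(len(coords))
    if solver == "nnls":
        for i, (x, y, s) in enumerate(coords):
            w, _ = nnls(design, z[x, y, s])
            total = w.sum()
            ratios[i] = w[0] / total if total > 0 else 0.0
    elif solver == "ols":
        zc = z[search_mask]
        w, *_ = np.linalg.lstsq(design, zc.T, rcond=None)
        total = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios = np.where(total != 0, w[0] / total, 0.0)
    else:
        raise ValueError("solver must be 'nnls' or 'ols'")

    weight_map = np.full(img.shape3d, np.nan)
    weight_map[tuple(coords.T)] = ratios
    mask = np.zeros(img.shape3d, bool)
    mask[tuple(coords.T)] = ratios > threshold
    if not mask.any():
        raise ValueError(
            f"no voxel exceeds the class-1 weight-ratio threshold {threshold}; empty reference region"
        )
    ref_tac = img.data[mask].mean(axis=0)
    return ReferenceRegion(
        mask=mask,
        ref_tac=ref_tac,
        weight_map=weight_map,
        threshold=threshold,
        provenance={
            "stage": "svca.extract_reference",
            "threshold": threshold,
            "solver": solver,
            "n_selected": int(mask.sum()),
            "n_controls": classes.n_controls,
        },
    )
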