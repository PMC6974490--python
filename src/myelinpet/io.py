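"""NIfTI / JSON-sidecar / YAML I/O and provenance plumbing.

Every image on disk is NIfTI-1; dynamic series carry a JSON sidecar with
``frame_start_s`` / ``frame_duration_s`` (seconds from injection) and the
decay-correction state; derived maps carry their provenance dict as the
sidecar. Sidecars live next to the image with the extension swapped to
``.json``. Uncompressed ``.nii`` is the default so repeated runs are
byte-identical (gzip embeds header metadata).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .core import DynamicImage, FrameScheme, ParametricMap
from .phantom import PhantomSpec

__all__ = [
    "sidecar_path",
    "write_dynamic",
    "read_dynamic",
    "write_map",
    "read_map",
    "write_mask",
    "read_mask",
    "save_phantom_spec",
    "load_phantom_spec",
    "file_sha256",
    "check_same_grid",
]


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return p.with_name(name[: -len(ext)] + ".json")
    return p.with_suffix(".json")


def _write_json(path: Path, payload: dict[str, Any]) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


def write_dynamic(img: DynamicImage, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(img.data.astype(np.float64), img.affine), str(path))
    _write_json(
        sidecar_path(path),
        {
            **img.scheme.to_dict(),
            "decay_corrected": bool(img.decay_corrected),
            "units": "kBq/ml",
            "time_reference": "injection",
        },
    )
    return path


def read_dynamic(path: str | Path) -> DynamicImage:
    path = Path(path)
    nii = nib.load(str(path))
    side = json.loads(sidecar_path(path).read_text())
    scheme = FrameScheme.from_dict(side)
    return DynamicImage(
        data=np.asarray(nii.dataobj, float),
        scheme=scheme,
        voxel_size_mm=_voxel_size_from_affine(nii.affine),
        decay_corrected=bool(side.get("decay_corrected", True)),
        affine=np.asarray(nii.affine),
    )


def write_map(pmap: ParametricMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float64), pmap.affine), str(path))
    _write_json(
        sidecar_path(path),
        {"quantity": pmap.quantity, "units": pmap.units, "provenance": pmap.provenance},
    )
    return path


def read_map(path: str | Path) -> ParametricMap:
    path = Path(path)
    nii = nib.load(str(path))
    side = json.loads(sidecar_path(path).read_text())
    return ParametricMap(
        values=np.asarray(nii.dataobj, float),
        quantity=side["quantity"],
        units=side["units"],
        voxel_size_mm=_voxel_size_from_affine(nii.affine),
        provenance=side.get("provenance", {}),
        affine=np.asarray(nii.affine),
    )


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.int16), affine), str(path))
    if provenance is not None:
        _write_json(sidecar_path(path), {"provenance": provenance})
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int16)


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
    return path


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def check_same_grid(*images: Any) -> None:
    """Raise if paired inputs disagree on shape or affine."""
    shapes = []
    affines = []
    for obj in images:
        if isinstance(obj, DynamicImage):
            shapes.append(obj.shape3d)
            affines.append(obj.affine)
        elif isinstance(obj, ParametricMap):
            shapes.append(obj.values.shape)
            affines.append(obj.affine)
        else:
            shapes.append(np.asarray(obj).shape[:3])
            affines.append(None)
    if any(s != shapes[0] for s in shapes[1:]):
        raise ValueError(f"grid mismatch between paired inputs: {shapes}")
    ref = next((a for a in affines if a is not None), None)
    for a in affines:
        if a is not None and ref is not None and not np.allclose(a, ref):
            raise ValueError("affine mismatch between paired inputs")
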