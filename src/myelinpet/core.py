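"""Shared in-memory containers for dynamic PET data and derived maps.

Conventions used throughout the package:

* voxel indexing is 0-based; physical coordinates come from the NIfTI affine;
* activity concentrations are kBq/ml;
* frame times are stored in seconds on disk and in the :class:`FrameScheme`,
  but kinetic arithmetic (Logan, compartment models) runs in minutes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["FrameScheme", "DynamicImage", "ParametricMap", "parse_scheme", "format_scheme"]

_GROUP_RE = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class FrameScheme:
    """Timing of a dynamic acquisition: contiguous frames from injection.

    Attributes
    ----------
    start_s : ndarray
        Per-frame start time in seconds; ``start_s[0] == 0`` and frames are
        contiguous (each start equals the previous start plus its duration).
    duration_s : ndarray
        Per-frame duration in seconds, all positive.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("start_s and duration_s must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("a frame scheme needs at least one frame")
        if start[0] != 0:
            raise ValueError("first frame must start at injection (t = 0)")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        expected = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        if not np.allclose(start, expected):
            raise ValueError("frames must be contiguous: start[i+1] = start[i] + duration[i]")

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes — the time axis for kinetic fits."""
        return self.mid_s / 60.0

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1])

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "frame_start_s": self.start_s.tolist(),
            "frame_duration_s": self.duration_s.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FrameScheme":
        return cls(np.asarray(d["frame_start_s"], float), np.asarray(d["frame_duration_s"], float))


def parse_scheme(spec_text: str) -> FrameScheme:
    """Expand a compact frame-group string into a :class:`FrameScheme`.

    ``"8x15,3x60,5x120,5x300,5x600"`` describes 8 frames of 15 s, then 3 of
    60 s, and so on — 27 contiguous frames covering 90 min for the default
    acquisition.
    """
    durations: list[float] = []
    for group in str(spec_text).split(","):
        m = _GROUP_RE.match(group)
        if m is None:
            raise ValueError(f"malformed frame group {group!r}; expected COUNTxSECONDS")
        count, dur = int(m.group(1)), float(m.group(2))
        if count == 0:
            raise ValueError(f"frame group {group!r} has zero count")
        if dur <= 0:
            raise ValueError(f"frame group {group!r} has non-positive duration")
        durations.extend([dur] * count)
    dur = np.asarray(durations, float)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameScheme(start, dur)


def format_scheme(scheme: FrameScheme) -> str:
    """Inverse of :func:`parse_scheme`: run-length encode the durations."""
    parts = []
    dur = scheme.duration_s
    i = 0
    while i < dur.size:
        j = i
        while j < dur.size and dur[j] == dur[i]:
            j += 1
        d = dur[i]
        parts.append(f"{j - i}x{d:g}")
        i = j
    return ",".join(parts)


@dataclass
class DynamicImage:
    """4-D dynamic PET volume (x, y, z, frame) in kBq/ml with its timing.

    ``decay_corrected`` records whether frame values have already been
    corrected back to injection time; :func:`myelinpet.framing.decay_correct`
    refuses to correct twice.
    """

    data: np.ndarray
    scheme: FrameScheme
    voxel_size_mm: tuple[float, float, float]
    decay_corrected: bool = True
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicImage data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.scheme.n_frames:
            raise ValueError(
                f"frame axis ({self.data.shape[3]}) does not match scheme "
                f"({self.scheme.n_frames} frames)"
            )
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, **changes: Any) -> "DynamicImage":
        return replace(self, data=data, **changes)


@dataclass
class ParametricMap:
    """3-D map of a derived quantity (DVR, SUV, SUVR or CBF).

    ``provenance`` carries the stage parameters that produced the map
    (t*, window, reference description, ...) so any output can be traced.
    """

    values: np.ndarray
    quantity: str
    units: str
    voxel_size_mm: tuple[float, float, float]
    provenance: dict[str, Any] = field(default_factory=dict)
    affine: np.ndarray | None = None

    _QUANTITIES = ("DVR", "SUV", "SUVR", "CBF")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ParametricMap values must be 3-D")
        if self.quantity not in self._QUANTITIES:
            raise ValueError(f"quantity must be one of {self._QUANTITIES}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])
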