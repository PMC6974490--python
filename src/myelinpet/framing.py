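"""Frame arithmetic shared by every quantification stage.

F-18 decay correction, frame-window averaging and scheme parsing. The decay
half-life default is 109.77 min (fluorine-18); correction is referenced to
injection time (t = 0) and applied at frame midpoints.
"""

from __future__ import annotations

import numpy as np

from .core import DynamicImage, FrameScheme, format_scheme, parse_scheme

__all__ = [
    "F18_HALF_LIFE_MIN",
    "parse_scheme",
    "format_scheme",
    "decay_correct",
    "decay_factors",
    "window_average",
]

F18_HALF_LIFE_MIN = 109.77


def decay_factors(scheme: FrameScheme, half_life_min: float = F18_HALF_LIFE_MIN) -> np.ndarray:
    """Per-frame multiplicative correction factors exp(lambda * t_mid)."""
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    lam = np.log(2.0) / half_life_min
    return np.exp(lam * scheme.mid_min)


def decay_correct(img: DynamicImage, half_life_min: float = F18_HALF_LIFE_MIN) -> DynamicImage:
    """Correct frame activities for radioactive decay back to injection time.

    Each frame is multiplied by ``exp(ln2 * t_mid / T_half)``. The returned
    image carries ``decay_corrected=True``; passing an already-corrected image
    raises, so the correction can never be applied twice.
    """
    if img.decay_corrected:
        raise ValueError("image is already decay-corrected; refusing to correct twice")
    factors = decay_factors(img.scheme, half_life_min)
    return img.with_data(img.data * factors, decay_corrected=True)


def window_average(img: DynamicImage, t0_min: float, t1_min: float) -> np.ndarray:
    """Duration-weighted mean of frames whose midpoints fall in [t0, t1) min.

    This is how the late static image (e.g. the 70-90 min window used for
    SUV) is condensed from the dynamic series. Membership is decided by frame
    midpoint on a half-open interval so boundary frames are never counted in
    two adjacent windows.
    """
    if t1_min <= t0_min:
        raise ValueError("window must satisfy t1 > t0")
    mid = img.scheme.mid_min
    sel = (mid >= t0_min) & (mid < t1_min)
    if not np.any(sel):
        raise ValueError(f"no frame midpoint falls within [{t0_min}, {t1_min}) min")
    w = img.scheme.duration_s[sel]
    return np.tensordot(img.data[..., sel], w, axes=([3], [0])) / w.sum()
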