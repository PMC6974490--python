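"""Digital dynamic-PET/MR phantom with known ground truth.

The phantom emulates a 90-min 27-frame amyloid-tracer acquisition over a
spherical brain: a grey-matter shell (the reference tissue, simulated as a
one-tissue compartment driven by an analytic plasma input), a white-matter
core and spherical white-matter lesions (both simulated with the simplified
reference tissue model so their true DVR = 1 + BP_nd is known exactly), and a
configurable number of pure blood-pool voxels carrying the input-function
curve itself. It also emits T1/T2 lesion masks, a pCASL control/label/M0
triplet encoding a known CBF map, and DTI-like scalar maps generated as
linear functions of true DVR.

Everything downstream of acquisition (reference extraction, Logan DVR, SUV,
layer morphometry, CBF, ROC) can therefore be tested by parameter recovery
without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from scipy.signal import lfilter

from .core import DynamicImage, FrameScheme, parse_scheme
from .framing import F18_HALF_LIFE_MIN
from .perfusion import AslParams, delta_m_from_cbf

__all__ = [
    "FengInput",
    "PhantomSpec",
    "LesionSpec",
    "GroundTruth",
    "PhantomResult",
    "simulate_reference_tac",
    "simulate_target_tac",
    "build_phantom",
]

DEFAULT_SCHEME_SPEC = "8x15,3x60,5x120,5x300,5x600"

# tissue label codes in GroundTruth.label_map
LABEL_BG = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_BLOOD = 3
LABEL_LESION_BASE = 10  # lesion k -> 10 + k


@dataclass(frozen=True)
class FengInput:
    """Analytic tri-exponential plasma input curve.

    Cp(t) = (A1*t - A2 - A3) * exp(-l1*t) + A2*exp(-l2*t) + A3*exp(-l3*t)

    with t in minutes. The default coefficients are the classic bolus-shape
    parameters scaled so the peak is ~100 kBq/ml — the paper-free part of the
    simulation: any smooth, realistic, early-peaking input suffices for
    parameter-recovery tests since DVR is input-independent.
    """

    a1: float = 851.1225 * 0.07
    a2: float = 21.8798 * 0.07
    a3: float = 20.8113 * 0.07
    l1: float = 4.133859
    l2: float = 0.01043449
    l3: float = 0.1190996

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        t = np.asarray(t_min, float)
        cp = (
            (self.a1 * t - self.a2 - self.a3) * np.exp(-self.l1 * t)
            + self.a2 * np.exp(-self.l2 * t)
            + self.a3 * np.exp(-self.l3 * t)
        )
        return np.maximum(cp, 0.0)


def _fine_grid(scheme: FrameScheme, dt_s: float = 1.0) -> np.ndarray:
    """Uniform internal time grid (minutes) covering the whole scan."""
    n = int(round(scheme.total_s / dt_s))
    return np.arange(n + 1) * (dt_s / 60.0)


def _expconv(f: np.ndarray, k: float, t_min: np.ndarray) -> np.ndarray:
    """Convolution f (x) exp(-k t) on a uniform grid, exact for piecewise-
    linear f. Implemented as a first-order linear recurrence."""
    dt = float(t_min[1] - t_min[0])
    if k == 0.0:
        # plain running integral, trapezoidal
        out = np.zeros_like(f)
        out[1:] = np.cumsum(0.5 * dt * (f[1:] + f[:-1]))
        return out
    e = math.exp(-k * dt)
    a = (1.0 - e) / k
    b = (1.0 - e * (1.0 + k * dt)) / (k * k * dt)
    c_next, c_prev = a - b, b  # weights of f[n+1] and f[n]
    z = lfilter([c_next, c_prev], [1.0, -e], f)
    # fix the initial condition: lfilter starts from z0 = c_next*f0, we need y0 = 0
    n = np.arange(f.size)
    return z - (c_next * f[0]) * e**n


def _frame_average(curve: np.ndarray, t_min: np.ndarray, scheme: FrameScheme) -> np.ndarray:
    """Trapezoidal mean of a fine-grid curve over each frame interval."""
    dt = t_min[1] - t_min[0]
    cum = np.zeros_like(curve)
    cum[1:] = np.cumsum(0.5 * dt * (curve[1:] + curve[:-1]))
    start_idx = np.rint(scheme.start_s / (dt * 60.0)).astype(int)
    end_idx = np.rint(scheme.end_s / (dt * 60.0)).astype(int)
    dur_min = scheme.duration_s / 60.0
    return (cum[end_idx] - cum[start_idx]) / dur_min


def simulate_reference_tac(
    k1: float,
    k2: float,
    scheme: FrameScheme,
    input_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Frame-averaged one-tissue-compartment TAC driven by a plasma input.

    dC/dt = k1*Cp(t) - k2*C(t), C(0) = 0; k1, k2 in 1/min. The instantaneous
    curve is evaluated on a 1-s internal grid (exact for piecewise-linear
    input) and averaged over each frame.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("rate constants k1, k2 must be non-negative")
    if input_fn is None:
        input_fn = FengInput()
    t = _fine_grid(scheme, dt_s)
    cp = input_fn(t)
    curve = k1 * _expconv(cp, k2, t)
    return _frame_average(curve, t, scheme)


def _target_curve_fine(
    ref_fine: np.ndarray, t_min: np.ndarray, r1: float, k2: float, bp_nd: float
) -> np.ndarray:
    k2a = k2 / (1.0 + bp_nd)
    return r1 * ref_fine + (k2 - r1 * k2a) * _expconv(ref_fine, k2a, t_min)


def simulate_target_tac(
    ref_tac: np.ndarray,
    r1: float,
    k2: float,
    bp_nd: float,
    scheme: FrameScheme,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Frame-averaged target-tissue TAC under the simplified reference tissue
    model, so the true DVR of the output is exactly 1 + bp_nd.

    C_t(t) = R1*C_ref(t) + (k2 - R1*k2a) * [C_ref (x) exp(-k2a t)],
    k2a = k2/(1+BP_nd). ``ref_tac`` is the reference TAC sampled per frame;
    it is rebuilt on the internal 1-s grid by linear interpolation through
    the frame midpoints (anchored at C(0) = 0) before convolution.
    """
    ref_tac = np.asarray(ref_tac, float)
    if ref_tac.shape != (scheme.n_frames,):
        raise ValueError("ref_tac length does not match the frame scheme")
    if bp_nd < 0:
        raise ValueError("bp_nd must be non-negative")
    t = _fine_grid(scheme, dt_s)
    ref_fine = np.interp(t, np.concatenate([[0.0], scheme.mid_min]), np.concatenate([[0.0], ref_tac]))
    curve = _target_curve_fine(ref_fine, t, r1, k2, bp_nd)
    return _frame_average(curve, t, scheme)


@dataclass(frozen=True)
class LesionSpec:
    """One spherical white-matter lesion.

    ``center_vox`` in 0-based voxel coordinates; ``radius_mm`` physical.
    ``bp_nd`` is the binding potential of the lesion tissue (true DVR =
    1 + bp_nd). Optional gradients emulate graded demyelination:
    ``core_bp_nd`` ramps BP linearly from the centre to ``bp_nd`` at the
    boundary; ``rim_width_mm`` ramps BP from ``bp_nd`` at the boundary back
    to the surrounding white-matter BP over that distance outside the lesion.
    ``t1_visible`` lesions additionally appear (eroded to ``t1_fraction`` of
    the radius) in the T1 "black hole" mask.
    """

    center_vox: tuple[float, float, float]
    radius_mm: float
    bp_nd: float
    r1: float = 0.8
    k2: float = 0.12
    core_bp_nd: float | None = None
    rim_width_mm: float = 0.0
    t1_visible: bool = False
    t1_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.bp_nd < 0 or (self.core_bp_nd is not None and self.core_bp_nd < 0):
            raise ValueError("lesion BP_nd must be non-negative")


def _default_lesions() -> list[LesionSpec]:
    # two T2 lesions inside the WM core; DVR 1.28 matches the group-mean
    # T2-lesion binding the phantom is meant to emulate, 1.10 a severe one
    return [
        LesionSpec(center_vox=(9.0, 12.0, 12.0), radius_mm=5.0, bp_nd=0.28, t1_visible=True),
        LesionSpec(center_vox=(15.0, 12.0, 11.0), radius_mm=4.4, bp_nd=0.10),
    ]


def _default_tissue_params() -> dict[str, dict[str, float]]:
    return {
        "gm": {"k1": 0.30, "k2": 0.15},  # reference tissue, one-tissue model
        "wm": {"r1": 0.80, "k2": 0.12, "bp_nd": 0.44},  # true DVR 1.44
    }


def _default_cbf_params() -> dict[str, float]:
    # ml/100 g/min; wm matches healthy-control white matter, lesions ~11% lower
    return {"gm": 60.0, "wm": 33.73, "lesion": 30.05, "blood": 60.0}


def _default_dti_model() -> dict[str, tuple[float, float, float]]:
    # map name -> (intercept, slope vs true DVR, noise SD at noise_scale 1)
    return {
        "fa": (-0.13, 0.40, 0.02),
        "md": (1.9e-3, -0.8e-3, 4e-5),
        "ad": (2.4e-3, -0.8e-3, 4e-5),
        "rd": (1.7e-3, -0.8e-3, 4e-5),
    }


@dataclass
class PhantomSpec:
    """Full description of one synthetic dataset; identical specs (including
    seed) produce bit-identical phantoms."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    frame_scheme_spec: str = DEFAULT_SCHEME_SPEC
    tissue_params: dict[str, dict[str, float]] = field(default_factory=_default_tissue_params)
    lesions: list[LesionSpec] = field(default_factory=_default_lesions)
    blood_fraction_voxels: int = 30
    noise_scale: float = 0.0
    seed: int | None = None
    injected_dose_MBq: float = 300.0
    body_weight_kg: float = 75.0
    cbf_params: dict[str, float] = field(default_factory=_default_cbf_params)
    dti_model: dict[str, tuple[float, float, float]] = field(default_factory=_default_dti_model)
    asl_params: AslParams = field(default_factory=AslParams)
    n_asl_pairs: int = 30
    brain_radius_frac: float = 0.45  # of the smallest grid extent
    wm_radius_frac: float = 0.62  # of the brain radius
    apply_decay: bool = True
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid too small to host a brain phantom (min 8 voxels per axis)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.blood_fraction_voxels < 0:
            raise ValueError("blood_fraction_voxels must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.noise_scale > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_scale > 0")
        self.lesions = [ls if isinstance(ls, LesionSpec) else LesionSpec(**ls) for ls in self.lesions]

    @property
    def scheme(self) -> FrameScheme:
        return parse_scheme(self.frame_scheme_spec)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "frame_scheme_spec": self.frame_scheme_spec,
            "tissue_params": self.tissue_params,
            "lesions": [
                {
                    "center_vox": list(ls.center_vox),
                    "radius_mm": ls.radius_mm,
                    "bp_nd": ls.bp_nd,
                    "r1": ls.r1,
                    "k2": ls.k2,
                    "core_bp_nd": ls.core_bp_nd,
                    "rim_width_mm": ls.rim_width_mm,
                    "t1_visible": ls.t1_visible,
                    "t1_fraction": ls.t1_fraction,
                }
                for ls in self.lesions
            ],
            "blood_fraction_voxels": self.blood_fraction_voxels,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
            "injected_dose_MBq": self.injected_dose_MBq,
            "body_weight_kg": self.body_weight_kg,
            "cbf_params": self.cbf_params,
            "dti_model": {k: list(v) for k, v in self.dti_model.items()},
            "asl_params": self.asl_params.to_dict(),
            "n_asl_pairs": self.n_asl_pairs,
            "brain_radius_frac": self.brain_radius_frac,
            "wm_radius_frac": self.wm_radius_frac,
            "apply_decay": self.apply_decay,
            "half_life_min": self.half_life_min,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomSpec":
        d = dict(d)
        if "lesions" in d:
            d["lesions"] = [LesionSpec(center_vox=tuple(ls["center_vox"]), **{k: v for k, v in ls.items() if k != "center_vox"}) for ls in d["lesions"]]
        if "asl_params" in d and isinstance(d["asl_params"], dict):
            d["asl_params"] = AslParams(**d["asl_params"])
        if "dti_model" in d:
            d["dti_model"] = {k: tuple(v) for k, v in d["dti_model"].items()}
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulation truth: everything a recovery test needs."""

    dvr_map: np.ndarray  # true DVR per voxel (1.0 in reference tissue, 0 outside brain)
    label_map: np.ndarray  # integer tissue codes (LABEL_* / LABEL_LESION_BASE + k)
    reference_tac: np.ndarray  # noiseless decay-corrected GM TAC, kBq/ml per frame
    cbf_map_true: np.ndarray  # ml/100 g/min


@dataclass
class PhantomResult:
    img: DynamicImage
    truth: GroundTruth
    masks: dict[str, np.ndarray]  # brain, gm, wm, blood, t2_lesions (labelled), t1_lesions (labelled)
    asl: dict[str, np.ndarray]  # control (4D), label (4D), m0 (3D)
    scalar_maps: dict[str, np.ndarray]
    spec: PhantomSpec


def _sphere_mask(shape: tuple[int, int, int], center_vox: np.ndarray, radius_vox: float) -> np.ndarray:
    grids = np.ogrid[[slice(0, s) for s in shape]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    return d2 <= radius_vox**2


def build_phantom(spec: PhantomSpec) -> PhantomResult:
    """Voxelize the phantom and simulate every emitted modality.

    Sphere membership is a centre-inside test (no fractional partial-volume
    mixing) so the truth maps stay piecewise constant unless a lesion
    declares a BP gradient. Gaussian frame noise has SD =
    noise_scale * sqrt(C / dt_min) — the first-order counting-noise
    approximation for a frame of duration dt averaging concentration C.
    """
    scheme = spec.scheme
    shape = spec.grid_shape
    vox = spec.voxel_size_mm
    center = (np.asarray(shape, float) - 1.0) / 2.0
    brain_r_vox = spec.brain_radius_frac * min(shape)
    wm_r_vox = spec.wm_radius_frac * brain_r_vox

    brain = _sphere_mask(shape, center, brain_r_vox)
    wm = _sphere_mask(shape, center, wm_r_vox)
    gm = brain & ~wm

    label = np.zeros(shape, dtype=np.int16)
    label[gm] = LABEL_GM
    label[wm] = LABEL_WM

    gm_p = spec.tissue_params["gm"]
    wm_p = spec.tissue_params["wm"]
    wm_bp = float(wm_p["bp_nd"])

    # per-voxel BP / R1 / k2 fields inside white matter
    bp_field = np.full(shape, np.nan)
    r1_field = np.full(shape, np.nan)
    k2_field = np.full(shape, np.nan)
    bp_field[wm] = wm_bp
    r1_field[wm] = float(wm_p["r1"])
    k2_field[wm] = float(wm_p["k2"])

    t2_labels = np.zeros(shape, dtype=np.int16)
    t1_labels = np.zeros(shape, dtype=np.int16)
    idx_grids = np.indices(shape, dtype=float)

    for k, ls in enumerate(spec.lesions, start=1):
        c = np.asarray(ls.center_vox, float)
        r_vox = ls.radius_mm / vox
        d_vox = np.sqrt(sum((idx_grids[a] - c[a]) ** 2 for a in range(3)))
        core = d_vox <= r_vox
        if not np.any(core):
            raise ValueError(f"lesion {k} covers no voxel centre; increase its radius")
        if np.any(core & ~wm):
            raise ValueError(f"lesion {k} extends outside the white-matter compartment")
        if np.any(t2_labels[core] != 0):
            raise ValueError(f"lesion {k} overlaps another lesion")
        t2_labels[core] = k
        label[core] = LABEL_LESION_BASE + k
        r1_field[core] = ls.r1
        k2_field[core] = ls.k2
        if ls.core_bp_nd is None:
            bp_field[core] = ls.bp_nd
        else:  # linear centre-to-boundary gradient (graded demyelination)
            frac = np.clip(d_vox[core] / r_vox, 0.0, 1.0)
            bp_field[core] = ls.core_bp_nd + (ls.bp_nd - ls.core_bp_nd) * frac
        if ls.rim_width_mm > 0:  # perilesional transition back to WM BP
            rim_vox = ls.rim_width_mm / vox
            rim = (~core) & wm & (t2_labels == 0) & (d_vox <= r_vox + rim_vox)
            frac = (d_vox[rim] - r_vox) / rim_vox
            rim_bp = ls.bp_nd + (wm_bp - ls.bp_nd) * frac
            # nested rims: keep the more demyelinated (lower BP) value
            bp_field[rim] = np.minimum(bp_field[rim], rim_bp)
        if ls.t1_visible:
            t1_core = d_vox <= r_vox * ls.t1_fraction
            t1_labels[t1_core] = k

    # blood-pool voxels: early-peaking input-function TAC planted in GM
    rng = np.random.default_rng(spec.seed) if spec.seed is not None else np.random.default_rng(0)
    gm_idx = np.flatnonzero(label.ravel() == LABEL_GM)
    if spec.blood_fraction_voxels > gm_idx.size:
        raise ValueError("not enough grey-matter voxels to host the requested blood pool")
    blood_flat = rng.choice(gm_idx, size=spec.blood_fraction_voxels, replace=False)
    blood = np.zeros(shape, bool)
    blood.ravel()[blood_flat] = True
    label[blood] = LABEL_BLOOD

    # --- kinetics -----------------------------------------------------------
    input_fn = FengInput()
    t_fine = _fine_grid(scheme)
    cp_fine = input_fn(t_fine)
    ref_fine = float(gm_p["k1"]) * _expconv(cp_fine, float(gm_p["k2"]), t_fine)
    ref_tac = _frame_average(ref_fine, t_fine, scheme)
    blood_tac = _frame_average(cp_fine, t_fine, scheme)

    dvr_map = np.zeros(shape)
    dvr_map[label == LABEL_GM] = 1.0
    dvr_map[label == LABEL_BLOOD] = 1.0
    in_wm = np.isfinite(bp_field)
    dvr_map[in_wm] = 1.0 + bp_field[in_wm]

    data = np.zeros(shape + (scheme.n_frames,))
    data[label == LABEL_GM] = ref_tac
    data[label == LABEL_BLOOD] = blood_tac
    # group white-matter voxels by (quantized BP, R1, k2) and simulate one TAC
    # per kinetic group; quantization to 1e-3 bounds the DVR grouping error
    q = np.round(bp_field[in_wm], 3)
    groups = {}
    wm_coords = np.argwhere(in_wm)
    for row, (bp_q, r1_v, k2_v) in enumerate(zip(q, r1_field[in_wm], k2_field[in_wm])):
        groups.setdefault((bp_q, r1_v, k2_v), []).append(row)
    for (bp_q, r1_v, k2_v), rows in groups.items():
        tac = _frame_average(_target_curve_fine(ref_fine, t_fine, r1_v, k2_v, bp_q), t_fine, scheme)
        coords = wm_coords[rows]
        data[coords[:, 0], coords[:, 1], coords[:, 2]] = tac

    if spec.apply_decay:
        lam = math.log(2.0) / spec.half_life_min
        data = data * np.exp(-lam * scheme.mid_min)

    if spec.noise_scale > 0:
        dt_min = scheme.duration_s / 60.0
        sd = spec.noise_scale * np.sqrt(np.maximum(data, 0.0) / dt_min)
        data = data + rng.normal(0.0, 1.0, data.shape) * sd

    img = DynamicImage(
        data=data,
        scheme=scheme,
        voxel_size_mm=(vox, vox, vox),
        decay_corrected=not spec.apply_decay,
    )

    # --- ASL triplet --------------------------------------------------------
    cbf_true = np.zeros(shape)
    cbf_true[label == LABEL_GM] = spec.cbf_params["gm"]
    cbf_true[label == LABEL_BLOOD] = spec.cbf_params.get("blood", spec.cbf_params["gm"])
    cbf_true[label == LABEL_WM] = spec.cbf_params["wm"]
    cbf_true[label >= LABEL_LESION_BASE] = spec.cbf_params.get("lesion", spec.cbf_params["wm"])

    m0 = np.where(brain, 1000.0, 0.0)
    dm = delta_m_from_cbf(cbf_true, m0, spec.asl_params)
    base = 0.9 * m0
    n_pairs = spec.n_asl_pairs
    control = np.repeat((base + dm)[..., None], n_pairs, axis=3)
    label_vol = np.repeat(base[..., None], n_pairs, axis=3)
    if spec.noise_scale > 0:
        asl_sd = spec.noise_scale * 2.0
        control = control + rng.normal(0.0, asl_sd, control.shape)
        label_vol = label_vol + rng.normal(0.0, asl_sd, label_vol.shape)

    # --- DTI-like scalar maps ----------------------------------------------
    scalar_maps: dict[str, np.ndarray] = {}
    for name, (intercept, slope, noise_sd) in spec.dti_model.items():
        m = np.where(brain, intercept + slope * dvr_map, 0.0)
        if spec.noise_scale > 0:
            m = m + np.where(brain, rng.normal(0.0, noise_sd * spec.noise_scale, shape), 0.0)
        scalar_maps[name] = m

    truth = GroundTruth(
        dvr_map=dvr_map, label_map=label, reference_tac=ref_tac, cbf_map_true=cbf_true
    )
    masks = {
        "brain": brain,
        "gm": label == LABEL_GM,
        "wm": wm,
        "blood": blood,
        "t2_lesions": t2_labels,
        "t1_lesions": t1_labels,
    }
    asl = {"control": control, "label": label_vol, "m0": m0}
    return PhantomResult(img=img, truth=truth, masks=masks, asl=asl, scalar_maps=scalar_maps, spec=spec)
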