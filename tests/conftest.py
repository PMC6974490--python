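import dataclasses

import numpy as np
import pytest

from myelinpet import (
    LesionSpec,
    PhantomSpec,
    build_classes,
    build_phantom,
    parse_scheme,
    simulate_reference_tac,
)
from myelinpet.framing import decay_correct

DEFAULT_SCHEME_TEXT = "8x15,3x60,5x120,5x300,5x600"


@pytest.fixture(scope="session")
def scheme():
    return parse_scheme(DEFAULT_SCHEME_TEXT)


@pytest.fixture(scope="session")
def ref_tac(scheme):
    """Noiseless grey-matter (reference tissue) TAC on the default scheme."""
    return simulate_reference_tac(0.30, 0.15, scheme)


@pytest.fixture(scope="session")
def phantom_default():
    """Default noiseless phantom (two lesions, 30 blood voxels), decay-corrected."""
    res = build_phantom(PhantomSpec(seed=1))
    return res, decay_correct(res.img)


def make_recovery_spec(**overrides):
    """16-cube phantom whose tissues span BP_nd 0.10 / 0.28 / 0.44 / 1.0."""
    lesions = [
        LesionSpec(center_vox=(5.5, 7.5, 7.5), radius_mm=4.6, bp_nd=0.10),
        LesionSpec(center_vox=(9.5, 7.5, 7.5), radius_mm=4.6, bp_nd=0.28),
        LesionSpec(center_vox=(7.5, 5.5, 7.5), radius_mm=4.6, bp_nd=1.00),
    ]
    base = dict(grid_shape=(16, 16, 16), voxel_size_mm=3.0, lesions=lesions, seed=7)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_recovery():
    res = build_phantom(make_recovery_spec())
    return res, decay_correct(res.img)


@pytest.fixture(scope="session")
def control_classes():
    """Kinetic classes built from two lesion-free control phantoms."""
    imgs, gms, wms, brains = [], [], [], []
    for seed in (101, 102):
        ctl = build_phantom(PhantomSpec(lesions=[], seed=seed))
        imgs.append(decay_correct(ctl.img))
        gms.append(ctl.masks["gm"])
        wms.append(ctl.masks["wm"])
        brains.append(ctl.masks["brain"])
    return build_classes(imgs, gms, wms, brains)


def tissue_mask(result):
    """Brain voxels with reference-tissue-model kinetics (blood excluded:
    blood-pool voxels carry the plasma input curve, for which a
    reference-tissue DVR is undefined)."""
    return result.masks["brain"] & ~result.masks["blood"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replace_spec(spec, **kw):
    return dataclasses.replace(spec, **kw)
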