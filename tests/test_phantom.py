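"""Phantom kinetics against independent oracles, and generator contracts."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from myelinpet import (
    DynamicImage,
    FengInput,
    LesionSpec,
    PhantomSpec,
    build_phantom,
    cbf_map,
    logan_dvr,
    simulate_reference_tac,
    simulate_target_tac,
)
from myelinpet.phantom import _expconv, _fine_grid, _frame_average

from conftest import tissue_mask


class TestReferenceTac:
    def test_no_uptake_gives_zero_curve(self, scheme):
        assert np.all(simulate_reference_tac(0.0, 0.1, scheme) == 0)

    def test_zero_input_gives_zero_curve(self, scheme):
        tac = simulate_reference_tac(0.1, 0.05, scheme, input_fn=lambda t: np.zeros_like(t))
        assert np.all(tac == 0)

    def test_negative_rates_rejected(self, scheme):
        with pytest.raises(ValueError):
            simulate_reference_tac(-0.1, 0.05, scheme)
        with pytest.raises(ValueError):
            simulate_reference_tac(0.1, -0.05, scheme)

    def test_matches_stiff_ode_oracle(self, scheme):
        """One-tissue kinetics dC/dt = k1*Cp - k2*C integrated by LSODA."""
        k1, k2 = 0.1, 0.05
        inp = FengInput()
        sol = solve_ivp(
            lambda t, c: k1 * inp(np.array([t]))[0] - k2 * c,
            [0.0, 90.0],
            [0.0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        t = _fine_grid(scheme)
        oracle_frames = _frame_average(sol.sol(t)[0], t, scheme)
        tac = simulate_reference_tac(k1, k2, scheme)
        assert np.max(np.abs(tac - oracle_frames)) / oracle_frames.max() < 1e-4


class TestTargetTac:
    def test_identity_tissue_reproduces_reference(self, scheme, ref_tac):
        out = simulate_target_tac(ref_tac, r1=1.0, k2=0.2, bp_nd=0.0, scheme=scheme)
        # curve-scale tolerance: the only error is rebuilding the fine grid
        # from frame samples, largest in the fast early frames
        assert np.max(np.abs(out - ref_tac)) / ref_tac.max() < 0.01

    def test_logan_round_trip_recovers_planted_dvr(self, scheme, ref_tac):
        tgt = simulate_target_tac(ref_tac, r1=0.9, k2=0.15, bp_nd=0.4, scheme=scheme)
        img = DynamicImage(tgt[None, None, None, :], scheme, (1, 1, 1))
        dvr = logan_dvr(img, ref_tac, t_star_min=30.0).values[0, 0, 0]
        assert dvr == pytest.approx(1.4, abs=0.02)

    @pytest.mark.parametrize("bp_nd", [0.28, 0.44])
    def test_matches_fine_grid_convolution_oracle(self, scheme, ref_tac, bp_nd):
        """Independent oracle: direct quadrature of the convolution integral
        C_ref (x) exp(-k2a t) on a 0.25-s grid."""
        r1, k2 = 0.8, 0.12
        k2a = k2 / (1.0 + bp_nd)
        dt_s = 0.25
        t = _fine_grid(scheme, dt_s=dt_s)
        ref_fine = np.interp(
            t, np.concatenate([[0.0], scheme.mid_min]), np.concatenate([[0.0], ref_tac])
        )
        conv = np.array(
            [np.trapezoid(ref_fine[: i + 1] * np.exp(-k2a * (t[i] - t[: i + 1])), t[: i + 1])
             for i in range(0, t.size, 40)]
        )
        curve_pts = r1 * ref_fine[::40] + (k2 - r1 * k2a) * conv
        # compare the package's fine-grid target curve at the same instants
        ours = _expconv(ref_fine, k2a, t)
        curve_ours = (r1 * ref_fine + (k2 - r1 * k2a) * ours)[::40]
        assert np.max(np.abs(curve_ours - curve_pts)) / curve_pts.max() < 1e-3

    def test_negative_bp_rejected(self, scheme, ref_tac):
        with pytest.raises(ValueError):
            simulate_target_tac(ref_tac, 0.8, 0.12, -0.1, scheme)

    def test_mismatched_scheme_rejected(self, scheme, ref_tac):
        with pytest.raises(ValueError):
            simulate_target_tac(ref_tac[:-1], 0.8, 0.12, 0.3, scheme)


class TestBuildPhantom:
    def test_noiseless_wm_voxels_share_one_tac(self):
        res = build_phantom(PhantomSpec(lesions=[], noise_scale=0.0))
        wm_tacs = res.img.data[res.truth.label_map == 2]
        assert np.all(wm_tacs == wm_tacs[0])

    def test_exactly_requested_blood_voxels_planted(self):
        res = build_phantom(PhantomSpec(blood_fraction_voxels=30, seed=3))
        assert int(res.masks["blood"].sum()) == 30
        # blood voxels dominate summed activity over the first 60 s
        early = res.img.scheme.end_s <= 60
        score = res.img.data[..., early].sum(axis=-1)
        blood_min = score[res.masks["blood"]].min()
        other = res.masks["brain"] & ~res.masks["blood"]
        assert blood_min > score[other].max()

    def test_identical_spec_is_bit_identical_and_seed_changes_noise(self):
        a = build_phantom(PhantomSpec(noise_scale=0.2, seed=1))
        b = build_phantom(PhantomSpec(noise_scale=0.2, seed=1))
        c = build_phantom(PhantomSpec(noise_scale=0.2, seed=2))
        assert np.array_equal(a.img.data, b.img.data)
        assert not np.array_equal(a.img.data, c.img.data)

    def test_label_map_partitions_grid_and_masks_nest(self, phantom_default):
        res, _ = phantom_default
        lm = res.truth.label_map
        m = res.masks
        # every voxel exactly one label; masks reconstruct the label map
        n_labelled = (
            int((lm == 0).sum()) + int(m["gm"].sum()) + int((lm == 2).sum())
            + int(m["blood"].sum()) + int((lm >= 10).sum())
        )
        assert n_labelled == lm.size
        t1 = m["t1_lesions"] != 0
        t2 = m["t2_lesions"] != 0
        assert np.all(~t1 | t2)  # T1 subset of T2
        assert np.all(~t2 | m["wm"])  # T2 subset of WM

    def test_dvr_map_is_one_plus_bp(self, phantom_default):
        res, _ = phantom_default
        assert np.all(res.truth.dvr_map[res.masks["gm"]] == 1.0)
        wm_only = res.truth.label_map == 2
        assert np.allclose(res.truth.dvr_map[wm_only], 1.44)
        assert np.allclose(res.truth.dvr_map[res.masks["t2_lesions"] == 1], 1.28)

    def test_seed_required_with_noise(self):
        with pytest.raises(ValueError, match="seed"):
            PhantomSpec(noise_scale=0.1, seed=None)

    def test_lesion_outside_wm_rejected(self):
        with pytest.raises(ValueError, match="white-matter"):
            build_phantom(PhantomSpec(lesions=[LesionSpec(center_vox=(2, 2, 2), radius_mm=4.0, bp_nd=0.2)]))

    def test_asl_triplet_round_trips_to_true_cbf(self, phantom_default):
        res, _ = phantom_default
        cbf = cbf_map(res.asl["control"], res.asl["label"], res.asl["m0"], res.spec.asl_params)
        err = np.abs(cbf.values - res.truth.cbf_map_true)[res.masks["brain"]]
        assert err.max() < 0.1

    def test_scalar_maps_are_linear_in_true_dvr_when_noiseless(self, phantom_default):
        res, _ = phantom_default
        a, b, _ = res.spec.dti_model["fa"]
        brain = res.masks["brain"]
        assert np.allclose(res.scalar_maps["fa"][brain], a + b * res.truth.dvr_map[brain])

    def test_spec_yaml_round_trip(self, tmp_path):
        from myelinpet.io import load_phantom_spec, save_phantom_spec

        spec = PhantomSpec(seed=5, noise_scale=0.1)
        save_phantom_spec(spec, tmp_path / "spec.yaml")
        again = load_phantom_spec(tmp_path / "spec.yaml")
        assert again.to_dict() == spec.to_dict()
        assert np.array_equal(build_phantom(again).img.data, build_phantom(spec).img.data)


def test_noiseless_logan_recovery_across_bp_range(phantom_recovery):
    """Round trip of the whole generator: Logan on noiseless frames recovers
    every planted DVR (1.10, 1.28, 1.44, 2.0 plus GM at 1.0) within the
    frame-discretization budget."""
    res, img = phantom_recovery
    dvr = logan_dvr(img, res.truth.reference_tac, t_star_min=30.0, brain_mask=res.masks["brain"])
    tm = tissue_mask(res)
    err = np.abs(dvr.values[tm] - res.truth.dvr_map[tm])
    assert err.max() < 0.02
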