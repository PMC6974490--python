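"""Lesion mask algebra against brute-force all-pairs distance oracles."""

import numpy as np
import pytest

from myelinpet import (
    filter_small_lesions,
    impaired_wm_mask,
    intralesional_layers,
    nawm_mask,
    perilesional_rings,
)


def brute_force_rings(lesion_labels, wm, voxel_size, bounds, mode):
    """All-pairs oracle: per lesion, distance of every outside voxel to the
    nearest lesion voxel centre (in-plane only for 2D mode), banded, clipped
    to WM, excluding lesions; same-band overlaps excluded from all claimants."""
    vox = np.asarray(voxel_size, float)
    any_lesion = lesion_labels != 0
    ids = [int(k) for k in np.unique(lesion_labels) if k != 0]
    cand = {}
    for k in ids:
        les = np.argwhere(lesion_labels == k).astype(float)
        d = np.full(lesion_labels.shape, np.inf)
        for p in np.argwhere(np.ones_like(lesion_labels, dtype=bool)):
            if mode == "2d":
                rows = les[les[:, 2] == p[2]]
                if len(rows) == 0:
                    continue
                diff = (rows[:, :2] - p[:2]) * vox[:2]
            else:
                rows = les
                diff = (rows - p) * vox
            d[tuple(p)] = np.sqrt((diff**2).sum(axis=1)).min()
        cand[k] = [(d > lo) & (d <= hi) & wm & ~any_lesion for lo, hi in bounds]
    for b in range(len(bounds)):
        claims = sum(cand[k][b].astype(int) for k in ids)
        for k in ids:
            cand[k][b] = cand[k][b] & (claims == 1) & cand[k][b]
    return cand


class TestNawm:
    def test_no_lesions_gives_whole_wm(self):
        wm = np.zeros((4, 4, 4), bool)
        wm[1:3] = True
        empty = np.zeros_like(wm)
        assert np.array_equal(nawm_mask(wm, empty, empty), wm)

    def test_full_lesion_coverage_empties_nawm(self):
        wm = np.ones((3, 3, 3), bool)
        assert not nawm_mask(wm, np.zeros_like(wm), wm).any()

    def test_voxel_counting_with_one_sphere(self, phantom_default):
        res, _ = phantom_default
        t2 = res.masks["t2_lesions"]
        only1 = np.where(t2 == 1, 1, 0)
        nawm = nawm_mask(res.masks["wm"], np.zeros_like(only1), only1)
        assert int(nawm.sum()) == int(res.masks["wm"].sum()) - int((t2 == 1).sum())

    def test_lesion_outside_wm_warns(self):
        wm = np.zeros((3, 3, 3), bool)
        wm[0] = True
        t2 = np.zeros_like(wm, dtype=int)
        t2[2, 2, 2] = 1
        with pytest.warns(UserWarning, match="outside"):
            nawm_mask(wm, np.zeros_like(t2), t2)


class TestPerilesionalRings:
    def test_single_voxel_lesion_2d_is_in_plane_disk(self):
        shape = (11, 11, 3)
        lab = np.zeros(shape, dtype=int)
        lab[5, 5, 1] = 1
        wm = np.ones(shape, bool)
        ls = perilesional_rings(lab, wm, (1.0, 1.0, 1.0), bounds_mm=[(0, 4)], mode="2d")
        ring = ls.perilesional[1][0]
        # oracle: in-plane disk of radius 4 around (5,5) in slice 1 only
        ii, jj = np.mgrid[0:11, 0:11]
        disk = (ii - 5) ** 2 + (jj - 5) ** 2 <= 16
        disk[5, 5] = False
        expected = np.zeros(shape, bool)
        expected[:, :, 1] = disk
        assert np.array_equal(ring, expected)

    def test_degenerate_bounds_give_empty_ring(self):
        lab = np.zeros((5, 5, 5), dtype=int)
        lab[2, 2, 2] = 1
        ls = perilesional_rings(lab, np.ones((5, 5, 5), bool), (1, 1, 1), bounds_mm=[(0.0, 0.0)])
        assert not ls.perilesional[1][0].any()

    def test_rings_never_enter_any_lesion(self):
        lab = np.zeros((12, 12, 4), dtype=int)
        lab[3:5, 3:5, 1] = 1
        lab[6:8, 4:6, 1] = 2  # adjacent lesion
        wm = np.ones(lab.shape, bool)
        ls = perilesional_rings(lab, wm, (1, 1, 1), mode="2d")
        for k in (1, 2):
            for ring in ls.perilesional[k]:
                assert not (ring & (lab != 0)).any()

    @pytest.mark.parametrize("mode", ["2d", "3d"])
    def test_matches_brute_force_oracle(self, mode, rng):
        shape = (14, 14, 8)
        lab = np.zeros(shape, dtype=int)
        lab[3:6, 4:7, 2:5] = 1
        lab[9:11, 8:10, 3:6] = 2
        wm = rng.random(shape) < 0.8
        wm[lab != 0] = True
        vox = (1.5, 1.5, 1.5) if mode == "3d" else (1.5, 1.5, 3.0)
        bounds = [(0.0, 4.0), (4.0, 8.0)]
        ls = perilesional_rings(lab, wm, vox, bounds_mm=bounds, mode=mode)
        oracle = brute_force_rings(lab, wm, vox, bounds, mode)
        for k in (1, 2):
            for b in range(2):
                assert np.array_equal(ls.perilesional[k][b], oracle[k][b]), (k, b, mode)

    def test_anisotropic_in_plane_voxels_rejected_in_2d(self):
        lab = np.zeros((4, 4, 4), dtype=int)
        lab[1, 1, 1] = 1
        with pytest.raises(ValueError, match="in-plane"):
            perilesional_rings(lab, np.ones((4, 4, 4), bool), (1.0, 2.0, 1.0), mode="2d")


class TestIntralesionalLayers:
    def test_sphere_splits_into_shell_and_core(self):
        shape = (11, 11, 11)
        ii, jj, kk = np.mgrid[0:11, 0:11, 0:11]
        lab = (((ii - 5) ** 2 + (jj - 5) ** 2 + (kk - 5) ** 2) <= 16).astype(int)
        ls = intralesional_layers(lab, (1.0, 1.0, 1.0), n_layers=2)
        outer, inner = ls.intralesional[1]
        # brute-force depth: distance to nearest outside voxel centre
        core = lab == 1
        out_coords = np.argwhere(~core).astype(float)
        depth = np.zeros(core.shape)
        for p in np.argwhere(core):
            depth[tuple(p)] = np.sqrt(((out_coords - p) ** 2).sum(axis=1)).min()
        dmax = depth[core].max()
        exp_inner = core & (depth > dmax / 2)
        exp_outer = core & ~exp_inner
        assert np.array_equal(inner, exp_inner)
        assert np.array_equal(outer, exp_outer)
        # exact partition
        assert not (outer & inner).any()
        assert np.array_equal(outer | inner, core)

    def test_single_layer_is_whole_lesion(self):
        lab = np.zeros((5, 5, 5), dtype=int)
        lab[1:4, 1:4, 1:4] = 1
        ls = intralesional_layers(lab, (1, 1, 1), n_layers=1)
        assert np.array_equal(ls.intralesional[1][0], lab == 1)

    def test_slab_lesion_gives_parallel_slabs(self):
        # infinite-in-plane slab, 4 voxels thick: depth depends on z only
        lab = np.zeros((6, 6, 8), dtype=int)
        lab[:, :, 2:6] = 1
        ls = intralesional_layers(lab, (1.0, 1.0, 1.0), n_layers=2)
        outer, inner = ls.intralesional[1]
        assert np.array_equal(np.unique(np.argwhere(outer)[:, 2]), [2, 5])
        assert np.array_equal(np.unique(np.argwhere(inner)[:, 2]), [3, 4])

    def test_single_voxel_lesion_degenerates_with_warning(self):
        lab = np.zeros((5, 5, 5), dtype=int)
        lab[2, 2, 2] = 1
        with pytest.warns(UserWarning, match="too small"):
            ls = intralesional_layers(lab, (1, 1, 1), n_layers=2)
        assert ls.intralesional[1][0][2, 2, 2]
        assert not ls.intralesional[1][1].any()


class TestFilterSmallLesions:
    def test_small_dropped_large_kept(self):
        lab = np.zeros((20, 20, 20), dtype=int)
        lab[2, 2, 2] = 1  # ~1.24 mm equivalent diameter at 1 mm voxels
        ii, jj, kk = np.mgrid[0:20, 0:20, 0:20]
        lab[((ii - 12) ** 2 + (jj - 12) ** 2 + (kk - 12) ** 2) <= 9] = 2  # 6 mm sphere
        out, report = filter_small_lesions(lab, (1.0, 1.0, 1.0), min_diameter_mm=4.3)
        assert report == {"retained": 1, "dropped": 1}
        assert not (out == 1).any() and (out == 2).any()

    def test_idempotent(self, phantom_default):
        res, _ = phantom_default
        once, _ = filter_small_lesions(res.masks["t2_lesions"], (2.0, 2.0, 2.0))
        twice, rep = filter_small_lesions(once, (2.0, 2.0, 2.0))
        assert np.array_equal(once, twice) and rep["dropped"] == 0

    def test_retains_planted_lesions_at_or_above_resolution(self, phantom_default):
        res, _ = phantom_default
        # both default lesions (5.0 and 4.4 mm radius spheres) exceed 4.3 mm diameter
        out, report = filter_small_lesions(res.masks["t2_lesions"], (2.0, 2.0, 2.0))
        assert report["retained"] == 2


class TestImpairedWm:
    def test_cutoff_arithmetic_from_reference_statistics(self):
        # healthy-control white matter DVR 1.44 +/- 0.11 -> cutoff 1.2244
        dvr = np.full((2, 2, 2), 1.20)
        wm = np.ones((2, 2, 2), bool)
        impaired, unaffected, cutoff = impaired_wm_mask(dvr, wm, 1.44, 0.11)
        assert cutoff == pytest.approx(1.44 - 1.96 * 0.11)
        assert np.all(impaired) and not unaffected.any()

    def test_map_at_reference_mean_is_unimpaired(self):
        dvr = np.full((3, 3, 3), 1.44)
        wm = np.ones((3, 3, 3), bool)
        impaired, unaffected, _ = impaired_wm_mask(dvr, wm, 1.44, 0.11)
        assert not impaired.any() and np.array_equal(unaffected, wm)

    def test_partition_of_wm(self, rng):
        dvr = rng.normal(1.4, 0.2, (6, 6, 6))
        wm = rng.random((6, 6, 6)) < 0.5
        impaired, unaffected, _ = impaired_wm_mask(dvr, wm, 1.44, 0.11)
        assert np.array_equal(impaired | unaffected, wm)
        assert not (impaired & unaffected).any()

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            impaired_wm_mask(np.ones((1, 1, 1)), np.ones((1, 1, 1), bool), 1.44, 0.0)
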