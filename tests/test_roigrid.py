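import numpy as np
import pytest

from alertfmri import roigrid as rg
from alertfmri.bold_synth import make_brain_geometry
from alertfmri.errors import ConfigurationError, GeometryError
from alertfmri.glm import ActivationMap, GroupMap


def box_grid(shape, origin=(0.0, 0.0, 0.0)):
    mask, affine = make_brain_geometry(shape)
    return mask, affine, rg.build_roi_grid(mask, affine, origin_mm=origin)


def stub_group(t=None, mean_psc=None, shape=(10, 10, 10), n=10):
    zeros = np.zeros(shape)
    return GroupMap(
        mean_psc=zeros if mean_psc is None else mean_psc,
        sem=zeros.copy(),
        t=zeros if t is None else t,
        p=np.ones(shape),
        n_subjects=n,
        mask=np.ones(shape, bool),
        affine=np.eye(4),
    )


def brute_force_assignment(mask, affine, edge, origin):
    """Independent voxel-by-voxel cube assignment oracle."""
    out = {}
    for ijk in np.argwhere(mask):
        world = affine @ np.array([*ijk, 1.0])
        cube = tuple(int(np.floor((w - o) / edge)) for w, o in zip(world[:3], origin))
        out.setdefault(cube, []).append(tuple(ijk))
    return out


class TestBuildRoiGrid:
    def test_single_full_cube_has_125_voxels(self):
        # mask covers exactly one grid-aligned cube: centers 1.5..13.5 mm
        mask = np.ones((5, 5, 5), bool)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = 1.5
        grid = rg.build_roi_grid(mask, affine)
        assert grid.n_rois == 1
        assert grid.rois[0].n_voxels == 125

    def test_cube_volume_3375_mm3(self):
        _, _, grid = box_grid((10, 10, 10))
        assert grid.edge_mm**3 == 3375.0

    def test_30mm_box_gives_8_disjoint_rois(self):
        mask, affine, grid = box_grid((10, 10, 10))
        assert grid.n_rois == 8
        seen = set()
        for roi in grid.rois:
            vox = {tuple(v) for v in roi.voxel_indices}
            assert not (vox & seen)
            seen |= vox
        assert len(seen) == mask.sum()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        mask, affine = make_brain_geometry((10, 10, 10))
        mask = rng.random(mask.shape) < 0.5
        grid = rg.build_roi_grid(mask, affine)
        oracle = brute_force_assignment(mask, affine, 15.0, (0.0, 0.0, 0.0))
        assert grid.n_rois == len(oracle)
        for roi in grid.rois:
            cube = tuple(
                int(np.floor((c - o) / 15.0))
                for c, o in zip(roi.corner_mm, (0, 0, 0))
            )
            assert {tuple(v) for v in roi.voxel_indices} == set(oracle[cube])

    def test_partition_property_random_masks(self):
        rng = np.random.default_rng(11)
        base, affine = make_brain_geometry((10, 10, 10))
        for _ in range(50):
            mask = rng.random(base.shape) < rng.uniform(0.05, 0.9)
            if not mask.any():
                continue
            grid = rg.build_roi_grid(mask, affine)
            assert sum(r.n_voxels for r in grid.rois) == mask.sum()
            label = grid.label_volume()
            assert np.array_equal(label > 0, mask)

    def test_numbering_is_z_then_y_then_x(self):
        _, _, grid = box_grid((10, 10, 10))
        keys = [(r.corner_mm[2], r.corner_mm[1], r.corner_mm[0]) for r in grid.rois]
        assert keys == sorted(keys)

    def test_max_voxels_bound(self):
        _, _, grid = box_grid((20, 20, 20))
        assert all(r.n_voxels <= 125 for r in grid.rois)

    def test_hemisphere_labels(self):
        _, _, grid = box_grid((10, 10, 10))
        for roi in grid.rois:
            assert roi.hemisphere == ("L" if roi.center_mm[0] < 0 else "R")

    def test_sheared_affine_rejected(self):
        mask = np.ones((5, 5, 5), bool)
        affine = np.eye(4) * 3.0
        affine[3, 3] = 1.0
        affine[0, 1] = 0.5
        with pytest.raises(GeometryError):
            rg.build_roi_grid(mask, affine)

    def test_edge_not_multiple_of_voxel(self):
        mask, affine = make_brain_geometry((5, 5, 5))
        with pytest.raises(ConfigurationError):
            rg.build_roi_grid(mask, affine, edge_mm=10.0)

    def test_empty_mask(self):
        _, affine = make_brain_geometry((5, 5, 5))
        with pytest.raises(ConfigurationError):
            rg.build_roi_grid(np.zeros((5, 5, 5), bool), affine)


class TestRoiMeanPsc:
    def _amap(self, psc, shape=(10, 10, 10)):
        return ActivationMap(
            beta={}, residual_variance=np.zeros(shape), df_resid=10,
            mask=np.ones(shape, bool), affine=np.eye(4), psc={"CUE": psc},
        )

    def test_constant_map(self):
        _, _, grid = box_grid((10, 10, 10))
        means = rg.roi_mean_psc(self._amap(np.full((10, 10, 10), 3.25)), grid, "CUE")
        assert all(v == pytest.approx(3.25) for v in means.values())

    def test_half_positive_half_negative(self):
        _, _, grid = box_grid((10, 10, 10))
        psc = np.zeros((10, 10, 10))
        roi = grid.rois[0]
        half = roi.n_voxels // 2
        for sign, chunk in ((1.0, roi.voxel_indices[:half]), (-1.0, roi.voxel_indices[half:half * 2])):
            psc[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = sign
        means = rg.roi_mean_psc(self._amap(psc), grid, "CUE")
        assert means[roi.roi_id] == pytest.approx(0.0)

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(2)
        _, _, grid = box_grid((10, 10, 10))
        psc = rng.standard_normal((10, 10, 10))
        means = rg.roi_mean_psc(self._amap(psc), grid, "CUE")
        for roi in grid.rois:
            acc = [psc[tuple(v)] for v in roi.voxel_indices]
            assert abs(means[roi.roi_id] - sum(acc) / len(acc)) < 1e-12

    def test_geometry_mismatch(self):
        _, _, grid = box_grid((10, 10, 10))
        with pytest.raises(GeometryError):
            rg.roi_mean_psc(self._amap(np.zeros((5, 5, 5)), shape=(5, 5, 5)), grid, "CUE")


class TestSelectRois:
    def test_all_zero_map_selects_nothing(self):
        _, _, grid = box_grid((10, 10, 10))
        assert rg.select_rois(stub_group(), grid) == []

    def test_infinite_threshold_selects_nothing(self):
        _, _, grid = box_grid((10, 10, 10))
        t = np.full((10, 10, 10), 100.0)
        assert rg.select_rois(stub_group(t=t), grid, t_threshold=np.inf) == []

    def test_threshold_picks_hot_rois(self):
        _, _, grid = box_grid((10, 10, 10))
        t = np.zeros((10, 10, 10))
        hot = grid.rois[3]
        t[tuple(hot.voxel_indices.T)] = 5.0
        assert rg.select_rois(stub_group(t=t), grid, mirror=False) == [hot.roi_id]

    def test_negative_hotspots_count(self):
        _, _, grid = box_grid((10, 10, 10))
        t = np.zeros((10, 10, 10))
        cold = grid.rois[5]
        t[tuple(cold.voxel_indices.T)] = -6.0
        assert cold.roi_id in rg.select_rois(stub_group(t=t), grid, mirror=False)

    def test_invalid_threshold(self):
        _, _, grid = box_grid((10, 10, 10))
        with pytest.raises(ConfigurationError):
            rg.select_rois(stub_group(), grid, t_threshold=0.0)


class TestMirrorRule:
    def test_adds_contralateral_roi(self):
        _, _, grid = box_grid((10, 10, 10))
        left = next(r for r in grid.rois if r.center_mm[0] < 0)
        out = rg.apply_mirror_rule([left.roi_id], grid)
        centers = {grid.roi(rid).center_mm for rid in out}
        assert (-left.center_mm[0], left.center_mm[1], left.center_mm[2]) in centers
        assert len(out) == 2

    def test_idempotent_on_bilateral_selection(self):
        _, _, grid = box_grid((10, 10, 10))
        once = rg.apply_mirror_rule([grid.rois[0].roi_id], grid)
        assert rg.apply_mirror_rule(once, grid) == once

    def test_reflection_closure(self):
        _, _, grid = box_grid((20, 20, 20))
        rng = np.random.default_rng(0)
        pick = list(rng.choice([r.roi_id for r in grid.rois], 10, replace=False))
        out = rg.apply_mirror_rule(pick, grid)
        for rid in out:
            cx, cy, cz = grid.roi(rid).center_mm
            mirrored = next(
                (r for r in grid.rois if r.center_mm == (-cx, cy, cz)), None
            )
            if mirrored is not None:
                assert mirrored.roi_id in out

    def test_midline_roi_no_addition(self):
        # half-offset anchor puts ROI centers on x = 0
        mask, affine = make_brain_geometry((10, 10, 10))
        grid = rg.build_roi_grid(mask, affine, origin_mm=(-7.5, 0.0, 0.0))
        mid = next(r for r in grid.rois if abs(r.center_mm[0]) < 1e-9)
        assert mid.hemisphere == "midline"
        assert rg.apply_mirror_rule([mid.roi_id], grid) == [mid.roi_id]

    def test_asymmetric_grid_rejected(self):
        mask, affine = make_brain_geometry((10, 10, 10))
        grid = rg.build_roi_grid(mask, affine, origin_mm=(-5.0, 0.0, 0.0))
        with pytest.raises(GeometryError, match="origin"):
            rg.apply_mirror_rule([grid.rois[0].roi_id], grid)


class TestAssignNetworks:
    def test_sign_allocation(self):
        _, _, grid = box_grid((10, 10, 10))
        mean = np.zeros((10, 10, 10))
        pos, neg, zero = grid.rois[0], grid.rois[1], grid.rois[2]
        mean[tuple(pos.voxel_indices.T)] = 0.09
        mean[tuple(neg.voxel_indices.T)] = -0.04
        group = stub_group(mean_psc=mean)
        with pytest.warns(UserWarning, match="zero"):
            nets = rg.assign_networks(
                [pos.roi_id, neg.roi_id, zero.roi_id], group, grid
            )
        assert nets[pos.roi_id] == "CEN"
        assert nets[neg.roi_id] == "DMN"
        assert nets[zero.roi_id] == "none"

    def test_empty_selection_rejected(self):
        _, _, grid = box_grid((10, 10, 10))
        with pytest.raises(ConfigurationError):
            rg.assign_networks([], stub_group(), grid)


class TestNetworkMean:
    def test_two_roi_cen(self):
        sig = rg.network_mean(
            {0: 0.1, 1: 0.2, 2: -0.3}, {0: "CEN", 1: "CEN", 2: "DMN"}, "s1"
        )
        assert sig.cen_psc == pytest.approx(0.15)
        assert sig.dmn_psc == pytest.approx(-0.3)

    def test_single_roi_network(self):
        sig = rg.network_mean({5: 0.42, 6: -0.1}, {5: "CEN", 6: "DMN"})
        assert sig.cen_psc == pytest.approx(0.42)

    def test_18_plus_10_roi_oracle(self):
        rng = np.random.default_rng(9)
        vals = {i: float(v) for i, v in enumerate(rng.standard_normal(28))}
        nets = {i: ("CEN" if i < 18 else "DMN") for i in range(28)}
        sig = rg.network_mean(vals, nets)
        assert sig.cen_psc == pytest.approx(sum(vals[i] for i in range(18)) / 18)
        assert sig.dmn_psc == pytest.approx(sum(vals[i] for i in range(18, 28)) / 10)

    def test_empty_network_flagged(self):
        with pytest.warns(UserWarning, match="DMN"):
            sig = rg.network_mean({0: 0.1}, {0: "CEN"})
        assert np.isnan(sig.dmn_psc)


class TestTumorOverlap:
    def test_per_roi_hand_count(self):
        _, _, grid = box_grid((10, 10, 10))
        roi = grid.rois[0]
        tumor = np.zeros((10, 10, 10), bool)
        chunk = roi.voxel_indices[:25]
        tumor[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = True
        assert rg.tumor_overlap_per_roi([tumor], roi) == pytest.approx(20.0)

    def test_per_roi_bounds(self):
        _, _, grid = box_grid((10, 10, 10))
        roi = grid.rois[0]
        empty = np.zeros((10, 10, 10), bool)
        full = np.ones((10, 10, 10), bool)
        assert rg.tumor_overlap_per_roi([empty, empty], roi) == 0.0
        assert rg.tumor_overlap_per_roi([full, full, full], roi) == 100.0

    def test_per_subject_empty_and_full(self):
        _, _, grid = box_grid((10, 10, 10))
        selected = [r.roi_id for r in grid.rois[:3]]
        tumor = np.zeros((10, 10, 10), bool)
        assert rg.tumor_overlap_per_subject(tumor, grid, selected) == 0.0
        for rid in selected:
            ijk = grid.roi(rid).voxel_indices
            tumor[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
        assert rg.tumor_overlap_per_subject(tumor, grid, selected) == 100.0

    def test_per_subject_half_roi_among_28(self):
        # 28 equal 125-voxel ROIs: a tumor covering 62 voxels of one ROI
        # gives 100 * 62 / 3500 of the selected-voxel pool
        mask, affine = make_brain_geometry((35, 20, 5))
        grid = rg.build_roi_grid(mask, affine, origin_mm=(-52.5, -30.0, -7.5))
        assert grid.n_rois == 28
        assert all(r.n_voxels == 125 for r in grid.rois)
        tumor = np.zeros((35, 20, 5), bool)
        chunk = grid.rois[0].voxel_indices[:62]
        tumor[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = True
        selected = [r.roi_id for r in grid.rois]
        got = rg.tumor_overlap_per_subject(tumor, grid, selected)
        assert got == pytest.approx(100.0 * 62 / 3500)

    def test_monotone_under_growth(self):
        rng = np.random.default_rng(3)
        _, _, grid = box_grid((10, 10, 10))
        selected = [r.roi_id for r in grid.rois]
        tumor = rng.random((10, 10, 10)) < 0.1
        small = rg.tumor_overlap_per_subject(tumor, grid, selected)
        grown = tumor | (rng.random((10, 10, 10)) < 0.2)
        assert rg.tumor_overlap_per_subject(grown, grid, selected) >= small

    def test_empty_selection_rejected(self):
        _, _, grid = box_grid((10, 10, 10))
        with pytest.raises(ConfigurationError):
            rg.tumor_overlap_per_subject(np.zeros((10, 10, 10), bool), grid, [])

    def test_misaligned_mask_rejected(self):
        _, _, grid = box_grid((10, 10, 10))
        with pytest.raises(GeometryError):
            rg.tumor_overlap_per_subject(
                np.zeros((5, 5, 5), bool), grid, [grid.rois[0].roi_id]
            )
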