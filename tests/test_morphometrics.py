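"""Orientation recovery, occupancy/heatmap bookkeeping, axial profiles, SBR."""

import math

import numpy as np
import pytest

import crmbiofilm as cb
from crmbiofilm.morphometrics import colony_slice_indices

from conftest import IMM, NOISE_FREE, make_capsule


def fine_grid():
    return cb.Grid(extent_um=(12.0, 12.0, 12.0), voxel_xy_um=0.1, voxel_z_um=0.1,
                   z_below_um=0.0)


class TestPitchAngle:
    @pytest.mark.parametrize(
        "axis, expected",
        [
            ((1, 0, 0), 0.0),
            ((0, 0, 1), 90.0),
            ((1 / math.sqrt(2), 0, 1 / math.sqrt(2)), 45.0),
        ],
    )
    def test_reference_directions(self, axis, expected):
        assert cb.pitch_angle(axis) == pytest.approx(expected, abs=1e-9)

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert cb.pitch_angle(v) == pytest.approx(cb.pitch_angle(-v))
            assert 0 <= cb.pitch_angle(v) <= 90

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cb.pitch_angle((0.0, 0.0, 0.0))


class TestPrincipalAxis:
    @pytest.mark.parametrize("pitch", [0, 15, 30, 45, 60, 75])
    def test_single_capsule_recovery_within_2_degrees(self, pitch):
        # 6 x 0.8 um capsule on a 0.1 um isotropic grid
        cell = make_capsule(pitch, yaw_deg=30.0, centroid=(6.0, 6.0, 6.0))
        truth = cb.rasterize_cells([cell], fine_grid())
        idx = np.argwhere(truth.labels == 1)
        axis, evals = cb.principal_axis(idx, (0.1, 0.1, 0.1))
        assert cb.pitch_angle(axis) == pytest.approx(pitch, abs=2.0)
        assert evals[0] >= evals[1] >= evals[2] > 0

    def test_vertical_capsule(self):
        cell = make_capsule(90.0, centroid=(6.0, 6.0, 6.0))
        truth = cb.rasterize_cells([cell], fine_grid())
        axis, _ = cb.principal_axis(np.argwhere(truth.labels == 1), (0.1, 0.1, 0.1))
        assert cb.pitch_angle(axis) >= 88.0

    def test_cube_is_isotropic(self):
        idx = np.argwhere(np.ones((8, 8, 8), dtype=bool))
        axis, evals = cb.principal_axis(idx, (0.1, 0.1, 0.1))
        assert evals[0] == pytest.approx(evals[2], rel=1e-9)
        assert math.sqrt(evals[0] / evals[1]) < cb.ELONGATION_CUTOFF

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cb.principal_axis(np.array([[0, 0, 0], [1, 1, 1]]), (0.1, 0.1, 0.1))
        coplanar = np.array([[0, y, x] for y in range(4) for x in range(4)])
        with pytest.raises(ValueError, match="coplanar"):
            cb.principal_axis(coplanar, (0.1, 0.1, 0.1))


class TestMeasureCells:
    def test_five_cell_scene_pitch_recovery(self):
        grid = cb.Grid(extent_um=(40.0, 12.0, 10.0), z_below_um=1.0)
        pitches = [0.0, 10.0, 25.0, 40.0, 55.0]
        cells = [
            make_capsule(p, yaw_deg=15 * i, length=6.0, centroid=(6.0 + 7.0 * i, 6.0, 5.0))
            for i, p in enumerate(pitches)
        ]
        truth = cb.rasterize_cells(cells, grid)
        stack = cb.render_stack(truth, NOISE_FREE, IMM)
        labels = cb.segment_cells(stack, cb.SegmentationParams(exclude_slices_below_um=0.0))
        table = cb.measure_cells(labels)
        assert len(table) == 5
        measured = sorted(table.pitch_deg)
        for est, true in zip(measured, sorted(pitches)):
            assert est == pytest.approx(true, abs=2.0)

    def test_empty_labels_empty_table(self, blank_truth):
        stack = cb.render_stack(blank_truth, NOISE_FREE, IMM)
        labels = cb.segment_cells(stack)
        table = cb.measure_cells(labels)
        assert table.empty

    def test_sphere_scene_flagged_isotropic(self):
        grid = cb.Grid(extent_um=(12.0, 12.0, 8.0), z_below_um=0.0)
        spheres = [
            cb.CellSpec((4.0, 4.0, 4.0), 1.6, 1.6, (1.0, 0.0, 0.0)),
            cb.CellSpec((8.0, 8.0, 4.0), 1.6, 1.6, (1.0, 0.0, 0.0)),
        ]
        truth = cb.rasterize_cells(spheres, grid)
        table = cb.measure_cells(_labels_from_truth(truth))
        assert table.flag_isotropic.all()
        summary = cb.angle_summary(table[~table.flag_isotropic].pitch_deg)
        assert summary["n"] == 0
        assert summary["mean_deg"] is None

    def test_length_estimate_tracks_true_length(self):
        cell = make_capsule(20.0, length=8.0, centroid=(6.0, 6.0, 6.0))
        truth = cb.rasterize_cells([cell], fine_grid())
        table = cb.measure_cells(_labels_from_truth(truth))
        assert table.length_est_um[0] == pytest.approx(8.0, rel=0.15)


def _labels_from_truth(truth):
    return cb.LabelVolume(
        labels=truth.labels, grid=truth.grid,
        n_labels=int(truth.labels.max()), threshold=0.0,
        params=cb.SegmentationParams(),
    )


class TestAngleSummary:
    def test_worked_example(self):
        s = cb.angle_summary([10, 20, 40], thresholds=[30])
        assert s["mean_deg"] == pytest.approx(23.333, abs=1e-3)
        assert s["frac_below"][30.0] == pytest.approx(2 / 3)

    def test_all_zero(self):
        s = cb.angle_summary([0, 0, 0], thresholds=[30, 45])
        assert s["mean_deg"] == 0
        assert all(v == 1 for v in s["frac_below"].values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cb.angle_summary([95.0])


class TestOccupancy:
    def test_full_coverage_slice_is_one(self):
        labels = np.zeros((5, 10, 10), dtype=np.int32)
        labels[2] = 1
        lv = cb.LabelVolume(labels=labels, grid=cb.Grid((2.0, 2.0, 1.0), 0.2, 0.2, 0.0),
                            n_labels=1, threshold=0.0, params=cb.SegmentationParams())
        prof = cb.occupancy_profile(lv, np.ones((10, 10), bool))
        assert prof.occupancy[2] == 1.0
        assert (prof.occupancy.drop(2) == 0).all()
        assert prof.z_um.is_monotonic_increasing

    def test_matches_ground_truth_rasterization(self, layered_truth, labels_noise_free):
        roi = cb.colony_roi(labels_noise_free)
        est = cb.occupancy_profile(labels_noise_free, roi).occupancy.to_numpy()
        true = (layered_truth.labels[:, roi] > 0).mean(axis=1)
        assert np.abs(est - true).max() <= 0.02

    def test_empty_roi_rejected(self, labels_noise_free):
        with pytest.raises(ValueError):
            cb.occupancy_profile(labels_noise_free, np.zeros(
                labels_noise_free.labels.shape[1:], bool))

    def test_colony_slice_indices_ordering(self, labels_noise_free):
        prof = cb.occupancy_profile(labels_noise_free, np.ones(
            labels_noise_free.labels.shape[1:], bool))
        idx = colony_slice_indices(prof.occupancy.to_numpy())
        assert idx["bottom"] <= idx["mid"] <= idx["top"]


class TestDensityHeatmap:
    def test_uniform_full_coverage(self):
        labels = np.ones((3, 24, 24), dtype=np.int32)
        lv = _heatmap_volume(labels)
        hm = cb.density_heatmap(lv, tile_um=2.4)
        assert np.all(hm == 1.0)

    def test_single_cell_single_tile(self):
        labels = np.zeros((3, 24, 24), dtype=np.int32)
        labels[1, 13:17, 14:18] = 1  # strictly inside the (1,1) tile (12 px tiles)
        hm = cb.density_heatmap(_heatmap_volume(labels), tile_um=2.4)
        assert (hm[1] > 0).sum() == 1
        assert hm[0].max() == 0 and hm[2].max() == 0

    def test_tile_weighted_mean_is_slice_occupancy(self, labels_noise_free):
        hm = cb.density_heatmap(labels_noise_free, tile_um=2.4)
        lab = labels_noise_free.labels
        t = int(round(2.4 / labels_noise_free.grid.voxel_xy_um))
        ny, nx = lab.shape[1:]
        weights = np.array(
            [[min(t, ny - j * t) * min(t, nx - i * t) for i in range(hm.shape[2])]
             for j in range(hm.shape[1])]
        )
        for zi in range(0, lab.shape[0], 10):
            field = (lab[zi] > 0).mean()
            weighted = (hm[zi] * weights).sum() / weights.sum()
            assert weighted == pytest.approx(field, abs=1e-12)

    def test_subvoxel_tile_rejected(self, labels_noise_free):
        with pytest.raises(ValueError):
            cb.density_heatmap(labels_noise_free, tile_um=0.01)


def _heatmap_volume(labels):
    ny = labels.shape[1]
    grid = cb.Grid((labels.shape[2] * 0.2, ny * 0.2, labels.shape[0] * 0.2),
                   0.2, 0.2, 0.0)
    return cb.LabelVolume(labels=labels, grid=grid, n_labels=int(labels.max()),
                          threshold=0.0, params=cb.SegmentationParams())


class TestAxialProfile:
    def test_constant_stack(self):
        data = np.full((10, 8, 8), 7.0, dtype=np.float32)
        grid = cb.Grid((1.6, 1.6, 2.0), 0.2, 0.2, 0.0)
        prof = cb.axial_intensity_profile(cb.ZStack(data=data, grid=grid))
        assert np.allclose(prof.mean_intensity, 7.0)
        assert prof.z_um.is_monotonic_increasing

    def test_glass_peak_at_interface(self, glass_stack_noise_free):
        prof = cb.axial_intensity_profile(glass_stack_noise_free)
        assert int(prof.mean_intensity.idxmax()) == glass_stack_noise_free.z_origin

    def test_exclusion_is_local(self):
        data = np.full((10, 8, 8), 10.0, dtype=np.float32)
        data[3, :4, :4] = 100.0
        grid = cb.Grid((1.6, 1.6, 2.0), 0.2, 0.2, 0.0)
        stack = cb.ZStack(data=data, grid=grid)
        full = cb.axial_intensity_profile(stack)
        excl = cb.axial_intensity_profile(stack, exclusion=(0, 4, 0, 4))
        assert excl.mean_intensity[3] < full.mean_intensity[3]
        others = [i for i in range(10) if i != 3]
        assert np.allclose(excl.mean_intensity[others], full.mean_intensity[others])

    def test_full_field_exclusion_rejected(self, imm_stack_noise_free):
        ny, nx = imm_stack_noise_free.data.shape[1:]
        with pytest.raises(ValueError):
            cb.axial_intensity_profile(imm_stack_noise_free, exclusion=(0, ny, 0, nx))


class TestSbr:
    def test_constructed_slice_ratio_two(self):
        # cell voxels at 172.4 over background 86.2 -> ratio exactly 2
        data = np.full((15, 40, 40), 86.2, dtype=np.float32)
        labels = np.zeros_like(data, dtype=np.int32)
        labels[5, 5:25, 5:25] = 1
        data[5, 5:25, 5:25] = 172.4
        grid = cb.Grid((8.0, 8.0, 3.0), 0.2, 0.2, 0.0)
        stack = cb.ZStack(data=data, grid=grid)
        lv = cb.LabelVolume(labels=labels, grid=grid, n_labels=1, threshold=0.0,
                            params=cb.SegmentationParams())
        res = cb.signal_background_ratio(stack, lv, z_offset_um=1.1, n_regions=20, seed=0)
        assert res.ratio == pytest.approx(2.0, abs=1e-6)

    def test_identical_intensities_ratio_one(self):
        data = np.full((15, 40, 40), 50.0, dtype=np.float32)
        labels = np.zeros_like(data, dtype=np.int32)
        labels[5, 5:25, 5:25] = 1
        grid = cb.Grid((8.0, 8.0, 3.0), 0.2, 0.2, 0.0)
        res = cb.signal_background_ratio(
            cb.ZStack(data=data, grid=grid),
            cb.LabelVolume(labels=labels, grid=grid, n_labels=1, threshold=0.0,
                           params=cb.SegmentationParams()),
            z_offset_um=1.1, n_regions=20, seed=0)
        assert res.ratio == pytest.approx(1.0)

    def test_insufficient_regions_error_names_class(self):
        data = np.full((15, 40, 40), 50.0, dtype=np.float32)
        labels = np.zeros_like(data, dtype=np.int32)  # no cells at all
        grid = cb.Grid((8.0, 8.0, 3.0), 0.2, 0.2, 0.0)
        with pytest.raises(ValueError, match="cell regions"):
            cb.signal_background_ratio(
                cb.ZStack(data=data, grid=grid),
                cb.LabelVolume(labels=labels, grid=grid, n_labels=0, threshold=0.0,
                               params=cb.SegmentationParams()),
                z_offset_um=1.1, n_regions=20, seed=0)

    def test_seeded_sampling_deterministic(self, imm_stack_noise_free, labels_noise_free):
        kwargs = dict(z_offset_um=2.1, n_regions=5, seed=11)
        a = cb.signal_background_ratio(imm_stack_noise_free, labels_noise_free, **kwargs)
        b = cb.signal_background_ratio(imm_stack_noise_free, labels_noise_free, **kwargs)
        assert a == b

    def test_fold_improvement_worked_example(self):
        assert round(cb.sbr_fold_improvement(15.8, 1.8), 1) == 8.8
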