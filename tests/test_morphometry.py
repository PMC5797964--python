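"""Feret poles, spindle shape metrics, aMTOC positions, sorting statistics."""

import math

import numpy as np
import pytest

import oospindle as oo
from oospindle import morphometry
from oospindle.errors import DegenerateSpindleError, SlabFractionError
from conftest import VOXEL, VOXEL_DIAGONAL
from oracles import all_pairs_feret_oracle, random_blob_mask

ISO = (1.0, 1.0, 1.0)


def _mask_from_voxels(voxels, shape):
    mask = np.zeros(shape, dtype=bool)
    for v in voxels:
        mask[v] = True
    return mask


class TestFeretExtremities:
    def test_two_voxel_3_4_5_triangle(self):
        mask = _mask_from_voxels([(0, 0, 0), (0, 3, 4)], (1, 5, 6))
        pole_a, pole_b, length, degenerate = oo.feret_extremities(mask, ISO)
        assert not degenerate
        assert length == pytest.approx(5.0)
        assert pole_a == (0.5, 0.5, 0.5)
        assert pole_b == (0.5, 3.5, 4.5)

    def test_single_voxel_is_degenerate(self):
        mask = _mask_from_voxels([(1, 1, 1)], (3, 3, 3))
        pole_a, pole_b, length, degenerate = oo.feret_extremities(mask, ISO)
        assert degenerate and length == 0.0 and pole_a == pole_b

    def test_matches_all_pairs_oracle_on_random_blobs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            mask = random_blob_mask(rng)
            voxel = (1.0, 0.5, 0.5)
            pole_a, pole_b, length, _ = oo.feret_extremities(mask, voxel)
            coords = (np.argwhere(mask) + 0.5) * np.asarray(voxel)
            _, _, oracle_length = all_pairs_feret_oracle(coords)
            assert length == pytest.approx(oracle_length, abs=1e-9)
            assert np.linalg.norm(np.asarray(pole_a) - np.asarray(pole_b)) == (
                pytest.approx(length)
            )

    def test_digitized_ellipsoid_long_axis(self, digitized_ellipsoid):
        _, _, length, _ = oo.feret_extremities(digitized_ellipsoid, VOXEL)
        assert length == pytest.approx(32.0, abs=VOXEL_DIAGONAL)


class TestSpindleMetrics:
    def test_ellipsoid_central_and_pole_widths(self, digitized_ellipsoid):
        model = oo.spindle_model_from_mask(digitized_ellipsoid, VOXEL)
        assert model.length_um == pytest.approx(32.0, abs=VOXEL_DIAGONAL)
        assert model.central_width_um == pytest.approx(16.0, abs=VOXEL_DIAGONAL)
        # analytic width of the ellipsoid cross-section at the slab edge
        assert model.pole_width_um == pytest.approx(9.6, abs=VOXEL_DIAGONAL)

    def test_sphere_length_equals_central_width(self):
        z, y, x = np.ogrid[:24, :24, :24]
        mask = (z - 12) ** 2 + (y - 12) ** 2 + (x - 12) ** 2 <= 10.0**2
        model = oo.spindle_model_from_mask(mask, ISO)
        diag = math.sqrt(3.0)
        assert model.length_um == pytest.approx(20.0, abs=diag)
        assert model.central_width_um == pytest.approx(20.0, abs=diag)

    def test_metrics_invariant_under_90_degree_rotation(self):
        rng = np.random.default_rng(23)
        mask = random_blob_mask(rng, shape=(20, 20, 20))
        base = oo.spindle_model_from_mask(mask, ISO)
        for axes in ((0, 1), (1, 2), (0, 2)):
            rotated = np.rot90(mask, k=1, axes=axes)
            model = oo.spindle_model_from_mask(rotated, ISO)
            assert model.length_um == pytest.approx(base.length_um, abs=1e-9)
            assert model.central_width_um == pytest.approx(
                base.central_width_um, abs=math.sqrt(3.0)
            )

    def test_empty_slab_raises(self):
        # only the two extreme voxels: central slab of 1% contains nothing
        mask = _mask_from_voxels([(0, 0, 0), (0, 0, 30)], (1, 1, 31))
        pole_a, pole_b, _, _ = oo.feret_extremities(mask, ISO)
        with pytest.raises(SlabFractionError):
            oo.spindle_metrics(mask, (pole_a, pole_b), ISO,
                               central_slab_fraction=0.01)


class TestMtocPositionMetrics:
    @pytest.fixture
    def straight_spindle(self):
        """Spindle voxel set along x from 0 to 30 µm with poles at the ends."""
        mask = np.zeros((3, 3, 32), dtype=bool)
        mask[1, 1, :31] = True
        model = morphometry.SpindleModel(
            pole_a=(0.0, 0.0, 0.0), pole_b=(0.0, 0.0, 30.0), length_um=30.0,
            central_width_um=1.0, pole_width_a_um=1.0, pole_width_b_um=1.0,
            axis_unit_vector=(0.0, 0.0, 1.0),
        )
        return model, mask

    def test_centroid_at_pole_has_zero_normalized_position(self, straight_spindle):
        model, mask = straight_spindle
        rec = oo.mtoc_position_metrics((0.0, 0.0, 0.0), 1.0, model, mask, ISO)
        assert rec.dist_pole_min_um == 0.0
        assert rec.normalized_position == 0.0

    def test_midpoint_normalizes_to_half(self, straight_spindle):
        model, mask = straight_spindle
        rec = oo.mtoc_position_metrics((0.0, 0.0, 15.0), 1.0, model, mask, ISO)
        assert rec.normalized_position == pytest.approx(0.5)

    def test_off_axis_closed_form_distance(self, straight_spindle):
        model, mask = straight_spindle
        rec = oo.mtoc_position_metrics((0.0, 5.0, 10.0), 1.0, model, mask, ISO)
        assert rec.dist_pole_min_um == pytest.approx(math.sqrt(125.0))
        assert rec.normalized_position == pytest.approx(math.sqrt(125.0) / 30.0)

    def test_border_distance_sign_flips_inside(self):
        z, y, x = np.ogrid[:20, :20, :20]
        mask = (z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2 <= 64
        model = morphometry.SpindleModel(
            pole_a=(10.5, 10.5, 2.5), pole_b=(10.5, 10.5, 18.5), length_um=16.0,
            central_width_um=16.0, pole_width_a_um=4.0, pole_width_b_um=4.0,
            axis_unit_vector=(0.0, 0.0, 1.0),
        )
        inside = oo.mtoc_position_metrics((10.5, 10.5, 10.5), 1.0, model, mask, ISO)
        outside = oo.mtoc_position_metrics((10.5, 10.5, 0.5), 1.0, model, mask, ISO)
        assert inside.border_distance_um < 0 < outside.border_distance_um

    def test_degenerate_spindle_is_rejected(self, straight_spindle):
        _, mask = straight_spindle
        degenerate = morphometry.SpindleModel(
            pole_a=(0.0, 0.0, 0.0), pole_b=(0.0, 0.0, 0.0), length_um=0.0,
            central_width_um=0.0, pole_width_a_um=0.0, pole_width_b_um=0.0,
            axis_unit_vector=(0.0, 0.0, 0.0), degenerate=True,
        )
        with pytest.raises(DegenerateSpindleError):
            oo.mtoc_position_metrics((1.0, 1.0, 1.0), 1.0, degenerate, mask, ISO)


def _records(positions):
    return [
        morphometry.MTOCRecord(
            centroid_um=(0.0, 0.0, 0.0), volume_um3=1.0, dist_pole_min_um=p,
            normalized_position=p, border_distance_um=0.0,
        )
        for p in positions
    ]


class TestSortingSd:
    def test_constant_positions_have_zero_sd(self):
        assert oo.sorting_sd(_records([0.05] * 6)) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_sample_sd(self):
        assert oo.sorting_sd(_records([0.1, 0.2, 0.3])) == pytest.approx(0.1)

    def test_fewer_than_two_records_is_missing(self):
        assert math.isnan(oo.sorting_sd(_records([0.2])))
        assert math.isnan(oo.sorting_sd([]))

    def test_scattered_exceeds_sorted_in_every_draw(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            scattered = oo.sorting_sd(_records(rng.uniform(0, 0.5, 20)))
            sorted_ = oo.sorting_sd(_records(rng.uniform(0, 0.02, 20)))
            assert scattered > sorted_


class TestSummarizeOocyte:
    @pytest.fixture
    def spindle(self):
        return morphometry.SpindleModel(
            pole_a=(0.0, 0.0, 0.0), pole_b=(0.0, 0.0, 30.0), length_um=30.0,
            central_width_um=12.0, pole_width_a_um=5.0, pole_width_b_um=6.0,
            axis_unit_vector=(0.0, 0.0, 1.0),
        )

    def test_counts_and_total_volume_are_additive(self, spindle):
        records = _records([0.1] * 20)
        for r in records:
            r.volume_um3 = 0.5
        summary = oo.summarize_oocyte(spindle, records)
        assert summary.n_mtocs == 20
        assert summary.total_mtoc_volume_um3 == pytest.approx(10.0)
        assert summary.pole_width_um == pytest.approx(5.5)

    def test_empty_records_flag_missing_sd(self, spindle):
        summary = oo.summarize_oocyte(spindle, [])
        assert summary.n_mtocs == 0
        assert summary.total_mtoc_volume_um3 == 0.0
        assert math.isnan(summary.sorting_sd)

    def test_end_to_end_sorted_scene_has_low_sd(self, scene_cache):
        truth, bf, mt, spot = scene_cache(
            41, n_mtocs=8, axial_fractions=[0.02] * 8, min_mtoc_separation=0.0
        )
        result = oo.analyze_channels(
            {"bright_field": bf, "microtubule": mt, "mtoc": spot},
            oo.PipelineConfig(),
        )
        assert result.summary.sorting_sd < 0.05
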