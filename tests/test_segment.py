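"""Filters, labeling, and the three channel segmentations."""

import numpy as np
import pytest
from scipy import ndimage

import oospindle as oo
from oospindle import segment
from oospindle.errors import (
    NoOocyteFoundError,
    NoSpindleFoundError,
    ParameterError,
    SizeError,
)
from oracles import (
    dense_gaussian_convolution,
    flood_fill_label_oracle,
    window_variance_oracle,
)

ISO = (1.0, 1.0, 1.0)


def _vol(data, voxel_size=ISO):
    return oo.MicroscopyVolume(np.asarray(data, dtype=float), voxel_size)


class TestVarianceFilter:
    def test_constant_volume_has_zero_variance(self):
        out = segment.variance_filter(_vol(np.full((7, 7, 7), 3.0)), radius_vox=1)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_single_bright_voxel_matches_window_oracle(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 10.0
        out = segment.variance_filter(_vol(data), radius_vox=1)
        np.testing.assert_allclose(out.data, window_variance_oracle(data, 1), atol=1e-9)

    def test_random_volume_matches_window_oracle(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 50, size=(7, 8, 9))
        out = segment.variance_filter(_vol(data), radius_vox=2)
        np.testing.assert_allclose(out.data, window_variance_oracle(data, 2), rtol=1e-8)

    def test_intensity_scaling_scales_variance_quadratically(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 10, size=(6, 6, 6))
        v1 = segment.variance_filter(_vol(data), radius_vox=1).data
        v2 = segment.variance_filter(_vol(3.0 * data), radius_vox=1).data
        np.testing.assert_allclose(v2, 9.0 * v1, rtol=1e-9)

    def test_volume_smaller_than_window_is_an_error(self):
        with pytest.raises(SizeError):
            segment.variance_filter(_vol(np.zeros((3, 10, 10))), radius_vox=2)


class TestGaussianFilter3D:
    def test_constant_volume_is_unchanged(self):
        out = segment.gaussian_filter_3d(_vol(np.full((8, 8, 8), 5.0)), radius_vox=2.0)
        np.testing.assert_allclose(out.data, 5.0, rtol=1e-12)

    def test_impulse_response_is_separable_kernel_product(self):
        data = np.zeros((15, 15, 15))
        data[7, 7, 7] = 1.0
        out = segment.gaussian_filter_3d(_vol(data), radius_vox=1.5)
        assert out.data.sum() == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(
            out.data, dense_gaussian_convolution(data, 1.5), atol=1e-12
        )

    def test_matches_dense_convolution_on_random_volume(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(0, 100, size=(9, 9, 9))
        out = segment.gaussian_filter_3d(_vol(data), radius_vox=2.0)
        np.testing.assert_allclose(out.data, dense_gaussian_convolution(data, 2.0),
                                   atol=1e-9)

    def test_total_intensity_is_conserved(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(0, 100, size=(20, 30, 30))
        out = segment.gaussian_filter_3d(_vol(data), radius_vox=2.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)


class TestDogFilter:
    def test_constant_volume_maps_to_zero(self):
        out = segment.dog_filter(_vol(np.full((10, 10, 10), 7.0)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_blob_response_peaks_at_blob_center(self):
        z, y, x = np.ogrid[:21, :21, :21]
        blob = np.exp(-(((z - 10) ** 2 + (y - 10) ** 2 + (x - 10) ** 2) / (2 * 1.5**2)))
        out = segment.dog_filter(_vol(blob), sigma_small_vox=1.5, sigma_large_vox=3.0)
        assert np.unravel_index(np.argmax(out.data), out.data.shape) == (10, 10, 10)

    def test_linear_ramp_interior_response_vanishes(self):
        ramp = np.broadcast_to(np.arange(32, dtype=float), (32, 32, 32)).copy()
        out = segment.dog_filter(_vol(ramp), sigma_small_vox=1.0, sigma_large_vox=2.0)
        interior = out.data[8:-8, 8:-8, 8:-8]
        assert np.abs(interior).max() <= 1e-6 * ramp.max()

    def test_sigma_ordering_is_enforced(self):
        with pytest.raises(ParameterError):
            segment.dog_filter(_vol(np.zeros((8, 8, 8))), 3.0, 1.5)


class TestLabelObjects:
    def test_matches_flood_fill_oracle_on_random_grids(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            mask = rng.random((20, 20, 20)) < 0.3
            ours = segment.label_objects(mask, ISO)
            oracle_labels, oracle_n = flood_fill_label_oracle(mask)
            assert ours.n_objects == oracle_n
            # identical partition up to label naming
            for lab in range(1, oracle_n + 1):
                voxels = oracle_labels == lab
                ours_labels = np.unique(ours.label_grid[voxels])
                assert ours_labels.size == 1 and ours_labels[0] > 0

    def test_volume_and_centroid_are_physical(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1:3, 2] = True  # two voxels along y
        objs = segment.label_objects(mask, (2.0, 0.5, 0.5))
        assert objs.n_objects == 1
        assert objs.volumes_um3[0] == pytest.approx(2 * 2.0 * 0.5 * 0.5)
        np.testing.assert_allclose(objs.centroids_um[0], [3.0, 1.0, 1.25])

    def test_empty_mask_yields_no_objects(self):
        objs = segment.label_objects(np.zeros((5, 5, 5), dtype=bool), ISO)
        assert objs.n_objects == 0


class TestExtractOocyteMask:
    def test_textured_disc_recovered_with_high_overlap(self, scene_cache):
        truth, bf, _, _ = scene_cache(0, gaussian_noise_sd=10.0)
        mask = oo.extract_oocyte_mask(bf)
        true_mask = truth.oocyte_mask()
        dice = 2 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum())
        assert dice >= 0.9
        _, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_flat_bright_field_raises(self):
        flat = _vol(np.full((16, 64, 64), 100.0), (1.0, 0.25, 0.25))
        with pytest.raises(NoOocyteFoundError):
            oo.extract_oocyte_mask(flat)

    def test_largest_of_two_discs_is_kept(self):
        rng = np.random.default_rng(31)
        data = np.full((16, 96, 96), 100.0)
        z, y, x = np.ogrid[:16, :96, :96]
        big = (z - 8) ** 2 + ((y - 30) / 1.0) ** 2 + ((x - 30) / 1.0) ** 2 < 22**2
        small = (z - 8) ** 2 + ((y - 75) / 1.0) ** 2 + ((x - 75) / 1.0) ** 2 < 8**2
        texture = rng.uniform(-40, 40, size=data.shape)
        data = data + texture * (big | small)
        mask = oo.extract_oocyte_mask(_vol(data, ISO))
        assert (mask & small).sum() == 0
        assert (mask & big).sum() > 0.5 * big.sum()


class TestSegmentSpindle:
    def test_bipolar_body_recovered_with_dice(self, scene_cache):
        truth, bf, mt, _ = scene_cache(0, gaussian_noise_sd=10.0)
        oocyte = oo.extract_oocyte_mask(bf)
        objs = oo.segment_spindle(mt, oocyte)
        assert objs.n_objects == 1
        mask = objs.mask(1)
        true_mask = truth.spindle_body_mask()
        dice = 2 * (mask & true_mask).sum() / (mask.sum() + true_mask.sum())
        assert dice >= 0.8

    def test_no_signal_raises(self):
        params = oo.SceneParams(n_mtocs=0, signal_level=0.0, gaussian_noise_sd=0.0)
        truth = oo.generate_scene(params, seed=1)
        bf, mt, _ = oo.render_volumes(truth)
        oocyte = oo.extract_oocyte_mask(bf)
        with pytest.raises(NoSpindleFoundError):
            oo.segment_spindle(mt, oocyte)

    def test_speckle_does_not_add_a_second_object(self, scene_cache):
        truth, bf, mt, _ = scene_cache(0)
        oocyte = oo.extract_oocyte_mask(bf)
        data = mt.data.copy()
        data[5, 30, 30] += 2000.0  # bright speckle far from the spindle
        objs = oo.segment_spindle(mt.with_data(data), oocyte)
        assert objs.n_objects == 1


class TestDetectMtocs:
    def test_noiseless_blobs_found_exactly_with_tight_centroids(self, scene_cache):
        truth, bf, _, spot = scene_cache(0)
        oocyte = oo.extract_oocyte_mask(bf)
        objs = oo.detect_mtocs(spot, oocyte)
        assert objs.n_objects == len(truth.mtoc_centers)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(np.array(truth.mtoc_centers)).query(objs.centroids_um)
        assert d.max() <= np.linalg.norm(truth.voxel_size)

    def test_scene_without_blobs_yields_zero_objects(self):
        params = oo.SceneParams(n_mtocs=0, gaussian_noise_sd=0.0)
        truth = oo.generate_scene(params, seed=5)
        bf, _, spot = oo.render_volumes(truth)
        oocyte = oo.extract_oocyte_mask(bf)
        assert oo.detect_mtocs(spot, oocyte).n_objects == 0

    def test_blobs_below_resolution_merge_into_one(self):
        params = oo.SceneParams(n_mtocs=2, axial_fractions=[0.45, 0.47],
                                radial_jitter=0.01, gaussian_noise_sd=0.0)
        truth = oo.generate_scene(params, seed=3)
        c = np.array(truth.mtoc_centers)
        assert np.linalg.norm(c[0] - c[1]) < 2.0  # closer than DoG resolution
        bf, _, spot = oo.render_volumes(truth)
        oocyte = oo.extract_oocyte_mask(bf)
        assert oo.detect_mtocs(spot, oocyte).n_objects == 1

    def test_detection_invariant_to_mtoc_ordering(self, scene_cache):
        import dataclasses

        truth, bf, _, spot = scene_cache(2)
        order = [3, 0, 5, 1, 4, 2]
        shuffled = dataclasses.replace(
            truth,
            mtoc_centers=[truth.mtoc_centers[i] for i in order],
            mtoc_radii=[truth.mtoc_radii[i] for i in order],
            mtoc_axial_fractions=[truth.mtoc_axial_fractions[i] for i in order],
        )
        _, _, spot2 = oo.render_volumes(shuffled)
        oocyte = oo.extract_oocyte_mask(bf)
        a = oo.detect_mtocs(spot, oocyte)
        b = oo.detect_mtocs(spot2, oocyte)
        assert a.n_objects == b.n_objects
        sa = a.centroids_um[np.lexsort(a.centroids_um.T)]
        sb = b.centroids_um[np.lexsort(b.centroids_um.T)]
        np.testing.assert_allclose(sa, sb, atol=1e-6)
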