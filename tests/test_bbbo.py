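"""Tests for registration, brain-wide fitting and BBBo classification."""

import numpy as np
import pytest

from barriermap import (
    DceSeries,
    ParamMaps,
    VoxelDims,
    bbbo_volume,
    classify_bbbo,
    fit_brain,
    group_ratio,
    register_series,
)
from barriermap.bbbo import BBBoResult

from _oracles import flood_fill_components


def _maps_from_dyn(dyn, r2=None):
    dyn = np.asarray(dyn, dtype=float)
    shape = dyn.shape
    r2 = np.full(shape, 0.95) if r2 is None else np.asarray(r2, dtype=float)
    zeros = np.zeros(shape)
    return ParamMaps(dyn, zeros, zeros, r2, np.ones(shape, dtype=bool))


class TestClassify:
    def test_all_zero_dyn_yields_empty_result(self):
        res = classify_bbbo(_maps_from_dyn(np.zeros((8, 8, 8))))
        assert res.n_voxels == 0
        assert res.clusters == ()
        assert not res.mask.any()

    def test_cluster_size_filter(self):
        """A 40-voxel component survives, a 12-voxel one does not."""
        dyn = np.zeros((12, 12, 12))
        dyn[1:6, 1:5, 1:3] = 20.0  # 5*4*2 = 40 voxels
        dyn[8:10, 8:11, 8:10] = 20.0  # 2*3*2 = 12 voxels
        res = classify_bbbo(_maps_from_dyn(dyn))
        assert res.n_voxels == 40
        assert res.clusters == ((1, 40),)

    def test_low_r2_excludes_high_dyn_voxels(self):
        dyn = np.zeros((10, 10, 10))
        dyn[2:6, 2:6, 2:6] = 20.0
        r2 = np.full((10, 10, 10), 0.5)
        res = classify_bbbo(_maps_from_dyn(dyn, r2))
        assert res.n_voxels == 0

    def test_conservation_and_min_cluster_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            dyn = np.where(rng.random((15, 15, 15)) < 0.25, 20.0, 0.0)
            res = classify_bbbo(_maps_from_dyn(dyn), min_cluster=5)
            assert res.n_voxels == sum(c for _, c in res.clusters)
            assert all(c >= 5 for _, c in res.clusters)
            assert res.n_voxels == int(res.mask.sum())

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_labeling_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(10):
            shape = tuple(rng.integers(5, 15, size=3))
            dyn = np.where(rng.random(shape) < 0.3, 20.0, 0.0)
            res = classify_bbbo(
                _maps_from_dyn(dyn), min_cluster=4, connectivity=connectivity
            )
            comps = flood_fill_components(dyn > 5, connectivity)
            kept = [c for c in comps if len(c) >= 4]
            assert res.n_voxels == sum(len(c) for c in kept)
            assert sorted(c for _, c in res.clusters) == sorted(len(c) for c in kept)
            want_mask = np.zeros(shape, dtype=bool)
            for c in kept:
                for v in c:
                    want_mask[v] = True
            assert np.array_equal(res.mask, want_mask)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        dyn = rng.uniform(0, 15, size=(12, 12, 12))
        r2 = rng.uniform(0.3, 1.0, size=(12, 12, 12))
        maps = _maps_from_dyn(dyn, r2)
        base = classify_bbbo(maps, min_cluster=3).n_voxels
        assert classify_bbbo(maps, r2_min=0.8, min_cluster=3).n_voxels <= base
        assert classify_bbbo(maps, dyn_min=8.0, min_cluster=3).n_voxels <= base
        assert classify_bbbo(maps, min_cluster=10).n_voxels <= base


class TestVolumesAndRatios:
    def test_voxel_volume_product(self):
        dims = VoxelDims(0.39, 0.39, 0.4)
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:3, :5, :2] = True  # 30 voxels
        res = BBBoResult(mask, ((1, 30),), 30, 30 * dims.volume_mm3,
                         mask.astype(int))
        assert bbbo_volume(res, dims) == pytest.approx(30 * 0.060840, rel=1e-9)

    def test_zero_voxels_zero_volume(self):
        empty = np.zeros((2, 2, 2), dtype=bool)
        res = BBBoResult(empty, (), 0, 0.0, empty.astype(int))
        assert bbbo_volume(res, VoxelDims(1, 1, 1)) == 0.0

    def test_group_ratio_reported_means(self):
        # treated 1785 vs sham 62.5 mean BBBo voxels -> 29-fold
        assert group_ratio(1785, 62.5) == 29

    def test_group_ratio_identity_and_guard(self):
        assert group_ratio(7.0, 7.0) == 1
        with pytest.raises(ZeroDivisionError):
            group_ratio(100, 0)


class TestFitBrain:
    def test_masking_contract(self, small_noiseless_phantom):
        series, truth = small_noiseless_phantom
        sub_mask = truth.brain_mask & ~truth.bbbo_mask
        maps = fit_brain(series, sub_mask)
        assert not maps.fitted_mask[truth.bbbo_mask].any()
        assert np.isnan(maps.dyn_map[truth.bbbo_mask]).all()

    def test_empty_mask_gives_empty_maps(self, small_noiseless_phantom):
        series, _ = small_noiseless_phantom
        maps = fit_brain(series, np.zeros(series.shape, dtype=bool))
        assert not maps.fitted_mask.any()

    def test_cluster_values_match_ground_truth_within_one_percent(
        self, small_noiseless_phantom
    ):
        series, truth = small_noiseless_phantom
        maps = fit_brain(series, truth.brain_mask)
        m = truth.bbbo_mask
        np.testing.assert_allclose(maps.dyn_map[m], truth.dyn_map[m], rtol=0.01)
        np.testing.assert_allclose(maps.aot_map[m], truth.aot_map[m],
                                   rtol=0.01, atol=1e-3)
        assert (maps.r2_map[m] > 0.999).all()

    def test_background_phantom_fits_flat(self, times8):
        rng = np.random.default_rng(1)
        vols = np.ones((10, 10, 10, 8)) * 500.0
        series = DceSeries(vols, times8)
        maps = fit_brain(series, np.ones((10, 10, 10), dtype=bool))
        assert maps.fitted_mask.all()
        assert np.nanmax(np.abs(maps.dyn_map)) < 1e-6

    def test_shape_mismatch_rejected(self, small_noiseless_phantom):
        series, _ = small_noiseless_phantom
        with pytest.raises(ValueError):
            fit_brain(series, np.ones((4, 4, 4), dtype=bool))


def _blob_series(times, shape=(24, 24, 16), shift=None):
    """Smooth random blobs, optionally shifted per frame, for registration."""
    rng = np.random.default_rng(99)
    from scipy.ndimage import gaussian_filter

    base = gaussian_filter(rng.random(shape), 2.0)
    base = 100 + 900 * (base - base.min()) / (base.max() - base.min())
    vols = np.stack([base] * len(times), axis=-1)
    if shift is not None:
        for fr in range(1, len(times)):
            vols[..., fr] = np.roll(base, shift, axis=0)
    return DceSeries(vols, times, VoxelDims(1.0, 1.0, 1.0))


class TestRegistration:
    def test_identity_case(self, times8):
        series = _blob_series(times8)
        out = register_series(series)
        for log in out.transforms[1:]:
            assert log["status"] == "registered"
            assert np.allclose(log["translation_mm"], 0.0, atol=0.05)
            assert np.allclose(log["rotation_rad"], 0.0, atol=0.05 * np.pi / 180)

    def test_known_two_voxel_shift_recovered(self, times8):
        series = _blob_series(times8, shift=2)
        out = register_series(series)
        log = out.transforms[1]
        assert log["status"] == "registered"
        # frames were rolled by +2 voxels along x (1 mm voxels)
        assert abs(abs(log["translation_mm"][0]) - 2.0) < 0.2
        assert abs(log["translation_mm"][1]) < 0.2
        assert abs(log["translation_mm"][2]) < 0.2

    def test_single_frame_rejected(self, times8):
        short = _single_frame(DceSeries(np.ones((8, 8, 8, 8)), times8))
        with pytest.raises(ValueError):
            register_series(short)


def _single_frame(series):
    """A one-frame series that skirts the times/frames invariant for the test."""
    obj = DceSeries.__new__(DceSeries)
    object.__setattr__(obj, "volumes", series.volumes[..., :1])
    object.__setattr__(obj, "times", series.times)
    object.__setattr__(obj, "voxel_dims", series.voxel_dims)
    return obj
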