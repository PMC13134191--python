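import numpy as np
import pytest
import pywt

import chondropipe as cp
from chondropipe.radiomics import (
    FeatureExtractionConfig,
    GLDM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    gldm_matrix,
    glszm_zones,
    logarithm_filter,
    ngtdm_table,
)

from oracles import (
    gldm_entries_bruteforce,
    glszm_zones_bruteforce,
    lae_bruteforce,
    ngtdm_bruteforce,
    ngtdm_strength_bruteforce,
    separable_convolve_bruteforce,
)


def _roi(values, mask=None, bin_width=25.0, voxel_volume=1.0):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return cp.discretize(values, mask, bin_width, voxel_volume)


class TestDiscretize:
    def test_constant_roi_single_level(self):
        roi = _roi(np.full((3, 3, 3), 7.0))
        assert roi.ng == 1
        assert set(np.unique(roi.levels[roi.mask])) == {1}

    def test_floor_formula_by_hand(self):
        vals = np.array([[[0.0, 24.9], [25.0, 50.0]]])
        roi = _roi(vals, bin_width=25.0)
        assert roi.levels[roi.mask].tolist() == [1, 1, 2, 3]

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random((4, 4, 3)) * 100
        a = _roi(vals)
        b = _roi(vals + 137.0)
        np.testing.assert_array_equal(a.levels, b.levels)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            _roi(np.zeros((3, 3, 3)), mask=np.zeros((3, 3, 3), bool))


class TestWaveletSubbands:
    def test_constant_volume_high_bands_vanish(self):
        bands = cp.wavelet_subbands(np.full((12, 12, 12), 5.0))
        for name, arr in bands.items():
            if "H" in name:
                np.testing.assert_allclose(arr, 0.0, atol=1e-10)

    def test_eight_shape_preserving_bands(self):
        vol = np.random.default_rng(1).normal(size=(10, 12, 8))
        bands = cp.wavelet_subbands(vol)
        assert len(bands) == 8
        assert all(b.shape == vol.shape for b in bands.values())

    def test_matches_direct_separable_convolution(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(8, 8, 8))
        w = pywt.Wavelet("coif1")
        lo = np.asarray(w.dec_lo) / np.sqrt(2.0)
        hi = np.asarray(w.dec_hi) / np.sqrt(2.0)
        bands = cp.wavelet_subbands(vol, "coif1")
        for key, filts in (("LLL", (lo, lo, lo)), ("HLH", (hi, lo, hi)),
                           ("HHH", (hi, hi, hi))):
            want = separable_convolve_bruteforce(vol, *filts)
            np.testing.assert_allclose(bands[key], want, rtol=1e-9, atol=1e-9)

    def test_axis_stripe_energy_concentration(self):
        # stripes varying along x only -> energy in H-on-x bands
        x = np.arange(8)
        vol = np.tile(((-1.0) ** x)[:, None, None], (1, 8, 8))
        bands = cp.wavelet_subbands(vol, "coif1")
        e_hll = (bands["HLL"] ** 2).sum()
        e_lhl = (bands["LHL"] ** 2).sum()
        e_llh = (bands["LLH"] ** 2).sum()
        assert e_hll > 100 * max(e_lhl, e_llh, 1e-12)

    def test_energy_conservation_orthogonal_periodic(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(size=(16, 16, 16))
        bands = cp.wavelet_subbands(vol, "coif1")
        total = sum((b ** 2).sum() for b in bands.values())
        assert total == pytest.approx((vol ** 2).sum(), rel=1e-6)

    def test_small_volume_rejected(self):
        with pytest.raises(ValueError, match="filter length"):
            cp.wavelet_subbands(np.zeros((4, 4, 2)))


class TestFirstOrder:
    def test_energy_arithmetic(self):
        f = cp.first_order_features(np.array([1.0, -1.0]), voxel_volume=2.0)
        assert f["Energy"] == 2.0
        assert f["TotalEnergy"] == 4.0

    def test_gaussian_kurtosis(self):
        x = np.random.default_rng(4).standard_normal(100_000)
        f = cp.first_order_features(x, voxel_volume=1.0)
        assert f["Kurtosis"] == pytest.approx(3.0, abs=0.1)
        assert f["Skewness"] == pytest.approx(0.0, abs=0.05)

    def test_constant_roi_sentinels(self):
        f = cp.first_order_features(np.full(20, 9.0), voxel_volume=1.0)
        assert f["Variance"] == 0.0
        assert f["Kurtosis"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_feature_count_and_names(self):
        f = cp.first_order_features(np.arange(10, dtype=float), voxel_volume=1.0)
        assert set(f) == set(FIRSTORDER_NAMES)
        assert len(f) == 19


class TestShape:
    def test_digital_ball_isotropic(self):
        grid = np.stack(np.meshgrid(*[np.arange(23)] * 3, indexing="ij"), -1)
        ball = ((grid - 11) ** 2).sum(-1) <= 100
        f = cp.shape_features(ball, (1, 1, 1))
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["Flatness"] == pytest.approx(1.0, abs=0.05)

    def test_rod_elongation_near_zero(self):
        rod = np.zeros((20, 5, 5), bool)
        rod[1:19, 2, 2] = True
        f = cp.shape_features(rod, (1, 1, 1))
        assert f["Elongation"] == pytest.approx(0.0, abs=1e-9)

    def test_ellipsoid_one_third(self):
        # semi-axes (30, 10, 10) mm at 1 mm isotropic spacing
        grid = np.stack(np.meshgrid(np.arange(65), np.arange(25), np.arange(25),
                                    indexing="ij"), -1).astype(float)
        c = np.array([32, 12, 12])
        u = (((grid - c) / [30, 10, 10]) ** 2).sum(-1)
        f = cp.shape_features(u <= 1, (1, 1, 1))
        assert f["Elongation"] == pytest.approx(1 / 3, abs=0.05)

    def test_voxel_volume_scales_with_spacing(self):
        m = np.zeros((6, 6, 6), bool)
        m[1:4, 1:4, 1:4] = True
        f = cp.shape_features(m, (0.6, 0.6, 4.5))
        assert f["VoxelVolume"] == pytest.approx(27 * 0.6 * 0.6 * 4.5)

    def test_max_diameter_of_rod(self):
        rod = np.zeros((10, 3, 3), bool)
        rod[0:10, 1, 1] = True
        f = cp.shape_features(rod, (2.0, 1.0, 1.0))
        assert f["Maximum3DDiameter"] == pytest.approx(18.0)


class TestGlszm:
    def test_single_uniform_zone(self):
        roi = _roi(np.full((2, 2, 2), 5.0))
        f = cp.glszm_features(roi)
        assert f["LargeAreaEmphasis"] == 64.0  # one zone of size 8 -> 8^2
        assert f["ZoneVariance"] == 0.0

    def test_all_distinct_levels(self):
        vals = (np.arange(8, dtype=float) * 100).reshape(2, 2, 2)
        roi = _roi(vals, bin_width=25.0)
        f = cp.glszm_features(roi)
        assert f["LargeAreaEmphasis"] == 1.0
        assert f["SmallAreaEmphasis"] == 1.0

    def test_zone_mass_equals_np(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            vals = rng.integers(0, 4, (6, 6, 6)).astype(float) * 25
            mask = rng.random((6, 6, 6)) < 0.7
            if not mask.any():
                continue
            roi = _roi(vals, mask)
            zones = glszm_zones(roi)
            assert zones[:, 1].sum() == roi.np_

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(15):
            vals = rng.integers(0, 4, (6, 6, 6)).astype(float) * 25
            mask = rng.random((6, 6, 6)) < 0.8
            if not mask.any():
                continue
            roi = _roi(vals, mask)
            got = cp.glszm_features(roi)["LargeAreaEmphasis"]
            assert got == pytest.approx(lae_bruteforce(roi.levels, mask), rel=1e-12)
            want = sorted(glszm_zones_bruteforce(roi.levels, mask))
            assert sorted(map(tuple, glszm_zones(roi))) == want


class TestGldm:
    def test_uniform_cube_center_dependence(self):
        roi = _roi(np.zeros((3, 3, 3)))
        entries = gldm_matrix(roi, alpha=0)
        deps = sorted(entries[:, 1])
        assert max(deps) == 27  # center voxel: 26 matching neighbors + itself
        assert len(entries) == 27

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        roi = _roi(np.ones((3, 3, 3)), mask)
        entries = gldm_matrix(roi)
        assert entries.tolist() == [[1, 1]]

    def test_matrix_mass_and_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            vals = rng.integers(0, 3, (5, 5, 4)).astype(float) * 25
            mask = rng.random((5, 5, 4)) < 0.7
            if not mask.any():
                continue
            roi = _roi(vals, mask)
            entries = gldm_matrix(roi, alpha=0)
            assert len(entries) == roi.np_  # sum of P equals Np
            want = sorted(gldm_entries_bruteforce(roi.levels, mask, 0))
            assert sorted(map(tuple, entries)) == want


class TestNgtdm:
    def test_constant_roi_strength_zero(self):
        roi = _roi(np.full((3, 3, 3), 4.0))
        f = cp.ngtdm_features(roi)
        assert f["Strength"] == 0.0
        assert f["Contrast"] == 0.0

    def test_checkerboard_matches_enumeration_oracle(self):
        grid = np.indices((4, 4, 4)).sum(axis=0) % 2
        vals = grid.astype(float) * 25
        roi = _roi(vals)
        got = cp.ngtdm_features(roi)["Strength"]
        want = ngtdm_strength_bruteforce(roi.levels, roi.mask)
        assert got == pytest.approx(want, rel=1e-12)

    def test_probability_normalization(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            vals = rng.integers(0, 5, (5, 5, 4)).astype(float) * 25
            mask = rng.random((5, 5, 4)) < 0.75
            if mask.sum() < 2:
                continue
            roi = _roi(vals, mask)
            n, p, s, nvp = ngtdm_table(roi)
            if nvp:
                assert p.sum() == pytest.approx(1.0, rel=1e-12)
            # cross-check the full table against brute force
            bn, bp, bs, bnvp = ngtdm_bruteforce(roi.levels, mask)
            assert nvp == bnvp
            for lvl, cnt in bn.items():
                assert n[lvl] == cnt
                assert s[lvl] == pytest.approx(bs[lvl], rel=1e-12)

    def test_wider_level_spacing_increases_strength(self):
        grid = np.indices((4, 4, 4)).sum(axis=0) % 2
        near = _roi(grid.astype(float) * 25)          # levels 1, 2
        far = _roi(grid.astype(float) * 50)           # levels 1, 3
        s_near = cp.ngtdm_features(near)["Strength"]
        s_far = cp.ngtdm_features(far)["Strength"]
        assert s_far > s_near
        assert ngtdm_strength_bruteforce(far.levels, far.mask) == pytest.approx(
            s_far, rel=1e-12)


class TestExtractAll:
    def _case(self, seed=0, shape=(24, 24, 10)):
        rng = np.random.default_rng(seed)
        data = rng.normal(500, 60, shape)
        vol = cp.VolumeGrid(data=data, spacing=(0.6, 0.6, 4.5))
        mask = np.zeros(shape, bool)
        mask[6:18, 6:18, 3:7] = True
        return vol, mask

    def test_registry_count_documented_constant(self):
        # 10 image filters x (19 firstorder + 16 glszm + 14 gldm + 5 ngtdm) + 14 shape
        expected = 10 * (19 + 16 + 14 + 5) + 14
        registry = cp.feature_registry()
        assert len(registry) == expected == 554
        assert len(set(registry)) == expected

    def test_deterministic(self):
        vol, mask = self._case()
        a = cp.extract_all(vol, mask)
        b = cp.extract_all(vol, mask)
        assert a == b

    def test_single_voxel_mask_sentinels(self):
        vol, _ = self._case()
        mask = np.zeros(vol.shape, bool)
        mask[5, 5, 5] = True
        rec = cp.extract_all(vol, mask)
        assert set(rec) == set(cp.feature_registry())
        assert all(np.isfinite(v) for v in rec.values())
        assert rec["original_shape_Elongation"] == 0.0

    def test_intensity_shift_invariance_of_textures(self):
        vol, mask = self._case(seed=1)
        shifted = cp.VolumeGrid(data=vol.data + 250.0, spacing=vol.spacing)
        a = cp.extract_all(vol, mask)
        b = cp.extract_all(shifted, mask)
        for name in a:
            cls = name.split("_")[1]
            if cls in ("glszm", "gldm", "ngtdm"):
                assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_empty_mask_rejected(self):
        vol, _ = self._case()
        with pytest.raises(ValueError, match="empty mask"):
            cp.extract_all(vol, np.zeros(vol.shape, bool))

    def test_all_values_finite(self):
        vol, mask = self._case(seed=2)
        rec = cp.extract_all(vol, mask)
        assert all(np.isfinite(v) for v in rec.values())


class TestLogarithmFilter:
    def test_preserves_range_and_order(self):
        rng = np.random.default_rng(9)
        x = rng.random((6, 6, 4)) * 900 + 50
        y = logarithm_filter(x)
        assert y.min() == pytest.approx(x.min())
        assert y.max() == pytest.approx(x.max())
        flat_x, flat_y = x.ravel(), y.ravel()
        order = np.argsort(flat_x)
        assert np.all(np.diff(flat_y[order]) >= -1e-9)
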