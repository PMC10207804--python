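import numpy as np
import pytest

from radcascade.features import (
    ExtractionConfig,
    WAVELET_LABELS,
    compute_first_order_features,
    compute_glcm_features,
    compute_glrlm_features,
    compute_glszm_features,
    compute_ngtdm_features,
    compute_run_and_dependence_features,
    compute_shape_features,
    extract_feature_vector,
    feature_names,
    wavelet_subbands,
)
from radcascade.volume_io import RoiMask, VolumeGrid
from conftest import ellipsoid_mask, make_roi


SPEC_GRID = [[1, 1, 2], [1, 2, 2]]  # the worked 2x3 single-slice example


class TestShape:
    def test_digital_ball_approaches_sphere(self):
        r = 20
        shape = (45, 45, 45)
        mask = RoiMask(ellipsoid_mask(shape, (r, r, r)), spacing=(1.0, 1.0, 1.0))
        f = compute_shape_features(mask)
        assert f["Sphericity"] >= 0.95
        assert f["MeshVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
        assert f["SurfaceArea"] == pytest.approx(4 * np.pi * r**2, rel=0.08)
        assert f["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)

    def test_dimensional_scaling_with_spacing(self):
        m = ellipsoid_mask((30, 24, 16), (10, 7, 5))
        f1 = compute_shape_features(RoiMask(m, spacing=(1.0, 1.0, 1.0)))
        f2 = compute_shape_features(RoiMask(m, spacing=(2.0, 2.0, 2.0)))
        assert f2["MeshVolume"] == pytest.approx(8 * f1["MeshVolume"], rel=1e-9)
        assert f2["VoxelVolume"] == pytest.approx(8 * f1["VoxelVolume"], rel=1e-9)
        assert f2["SurfaceArea"] == pytest.approx(4 * f1["SurfaceArea"], rel=1e-9)
        assert f2["Sphericity"] == pytest.approx(f1["Sphericity"], rel=1e-9)
        assert f2["MajorAxisLength"] == pytest.approx(2 * f1["MajorAxisLength"], rel=1e-9)

    def test_intensity_independent(self, small_volume_pair, rng):
        vol, mask = small_volume_pair
        cfg = ExtractionConfig()
        f1 = extract_feature_vector(vol, mask, cfg)
        vol2 = VolumeGrid(vol.data * 2.0, spacing=vol.spacing, origin=vol.origin)
        f2 = extract_feature_vector(vol2, mask, cfg)
        for name in feature_names(cfg):
            if "_shape_" in name:
                assert f1[name] == f2[name], name

    def test_single_voxel_mask_no_error(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        f = compute_shape_features(RoiMask(m, spacing=(1.0, 1.0, 1.0)))
        assert f["SurfaceArea"] > 0
        assert np.isfinite(list(f.values())).all()


class TestFirstOrder:
    def test_hand_example(self):
        f = compute_first_order_features(np.array([1.0, 2.0, 3.0, 4.0]), bin_width=1.0)
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Median"] == pytest.approx(2.5)
        assert f["Entropy"] == pytest.approx(2.0)  # 4 equally filled bins
        assert f["Uniformity"] == pytest.approx(0.25)

    def test_constant_input_conventions(self):
        f = compute_first_order_features(np.full(17, 3.3), bin_width=20.0)
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0

    def test_gaussian_kurtosis_is_non_excess(self):
        x = np.random.default_rng(7).normal(size=100_000)
        f = compute_first_order_features(x, bin_width=0.1)
        assert abs(f["Kurtosis"] - 3.0) < 0.1
        assert abs(f["Skewness"]) < 0.05

    def test_permutation_invariance(self, rng):
        x = rng.normal(10, 4, size=200)
        f1 = compute_first_order_features(x, bin_width=2.0)
        f2 = compute_first_order_features(rng.permutation(x), bin_width=2.0)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9), k

    def test_feature_count(self):
        f = compute_first_order_features(np.arange(10.0), bin_width=1.0)
        assert len(f) == 18


class TestGlcm:
    def test_hand_example_correlation_zero(self):
        roi = make_roi(SPEC_GRID)
        f = compute_glcm_features(roi, directions=[(0, 1, 0)])
        # symmetric pairs are uniform over {(1,1),(1,2),(2,1),(2,2)}
        assert f["Correlation"] == pytest.approx(0.0, abs=1e-12)
        assert f["JointEnergy"] == pytest.approx(0.25)
        assert f["MaximumProbability"] == pytest.approx(0.25)

    def test_constant_roi_conventions(self):
        roi = make_roi(np.ones((3, 3, 2), dtype=int))
        f = compute_glcm_features(roi)
        assert f["Correlation"] == 1.0
        assert f["Imc1"] == 0.0
        assert f["Imc2"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["MCC"] == 1.0

    def test_feature_count(self):
        f = compute_glcm_features(make_roi(SPEC_GRID))
        assert len(f) == 24


class TestGlszm:
    def test_hand_example(self):
        f = compute_glszm_features(make_roi(SPEC_GRID))
        # two 26-connected zones, both of size 3
        assert f["SmallAreaEmphasis"] == pytest.approx(1 / 9)
        assert f["LowGrayLevelZoneEmphasis"] == pytest.approx(0.625)
        assert f["SizeZoneNonUniformityNormalized"] == pytest.approx(1.0)

    def test_constant_roi_single_zone(self):
        s = 4 * 3 * 2
        f = compute_glszm_features(make_roi(np.ones((4, 3, 2), dtype=int)))
        assert f["SmallAreaEmphasis"] == pytest.approx(1 / s**2)
        assert f["SizeZoneNonUniformityNormalized"] == pytest.approx(1.0)
        assert f["ZonePercentage"] == pytest.approx(1 / s)


class TestRunsAndDependence:
    def test_hand_run_enumeration(self):
        roi = make_roi(np.array([[1, 1, 2, 2, 2]]))
        from radcascade.features import _glrlm_matrix

        R = _glrlm_matrix(roi.level_array, roi.n_levels, (0, 1, 0))
        assert R[0, 1] == 1  # level 1, length 2
        assert R[1, 2] == 1  # level 2, length 3
        assert R.sum() == 2

    def test_constant_roi_run_percentage(self):
        s = 6
        roi = make_roi(np.ones((1, s), dtype=int))
        f = compute_glrlm_features(roi, directions=[(0, 1, 0)])
        assert f["RunPercentage"] == pytest.approx(1 / s)

    def test_constant_roi_ngtdm_contrast_zero(self):
        f = compute_ngtdm_features(make_roi(np.ones((3, 3, 2), dtype=int)))
        assert f["Contrast"] == 0.0
        assert np.isfinite(f["Coarseness"])

    def test_combined_feature_count(self):
        f = compute_run_and_dependence_features(make_roi(SPEC_GRID))
        assert len(f) == 16 + 14 + 5


class TestWavelet:
    def test_constant_volume_highpass_zero(self):
        vol = np.full((8, 7, 6), 5.0)
        bands = wavelet_subbands(vol)
        assert list(bands) == WAVELET_LABELS
        np.testing.assert_allclose(bands["LLL"], 5.0 * 2**1.5, atol=1e-12)
        for lab in WAVELET_LABELS:
            assert bands[lab].shape == vol.shape
            if "H" in lab:
                np.testing.assert_allclose(bands[lab], 0.0, atol=1e-12)

    def test_impulse_gives_separable_tap_product(self):
        # correlate1d with a 2-tap filter places out[i] = w0*x[i-1] + w1*x[i]
        vol = np.zeros((9, 9, 9))
        c = 4
        vol[c, c, c] = 1.0
        lo = np.array([1.0, 1.0]) / np.sqrt(2)
        hi = np.array([-1.0, 1.0]) / np.sqrt(2)  # orthonormal Haar analysis pair
        taps = {"L": lo, "H": hi}
        bands = wavelet_subbands(vol)
        for lab in WAVELET_LABELS:
            resp = {}
            for ax in range(3):
                r = np.zeros(9)
                w = taps[lab[ax]]
                r[c] = w[1]
                r[c + 1] = w[0]
                resp[ax] = r
            expected = np.einsum("i,j,k->ijk", resp[0], resp[1], resp[2])
            np.testing.assert_allclose(bands[lab], expected, atol=1e-12, err_msg=lab)


class TestFullVector:
    def test_851_features_finite_and_ordered(self, small_volume_pair):
        vol, mask = small_volume_pair
        cfg = ExtractionConfig()
        fv = extract_feature_vector(vol, mask, cfg)
        names = feature_names(cfg)
        assert list(fv) == names
        assert len(fv) == 851
        vals = np.array(list(fv.values()))
        assert np.isfinite(vals).all()
        # composition: 107 original + 93 per sub-band
        orig = [n for n in names if n.startswith("original_")]
        assert len(orig) == 107
        for lab in WAVELET_LABELS:
            assert sum(n.startswith(f"wavelet-{lab}_") for n in names) == 93

    def test_intensity_shift_leaves_texture_unchanged(self, small_volume_pair):
        vol, mask = small_volume_pair
        cfg = ExtractionConfig()
        f1 = extract_feature_vector(vol, mask, cfg)
        shifted = VolumeGrid(vol.data + 250.0, spacing=vol.spacing, origin=vol.origin)
        f2 = extract_feature_vector(shifted, mask, cfg)
        for name in feature_names(cfg):
            fam = name.split("_")[1]
            if fam in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert f1[name] == pytest.approx(f2[name], abs=1e-9), name

    def test_degenerate_empty_mask_raises(self, small_volume_pair):
        from radcascade.volume_io import DegenerateRoiError

        vol, _ = small_volume_pair
        empty = RoiMask(np.zeros(vol.shape, dtype=bool), spacing=vol.spacing)
        with pytest.raises(DegenerateRoiError):
            extract_feature_vector(vol, empty)
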