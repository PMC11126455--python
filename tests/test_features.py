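"""Feature formulas: worked examples, formula oracles, bounds, table extraction."""

import numpy as np
import pandas as pd
import pytest

import droptex
from droptex.features import (
    EPS,
    FEATURE_COLUMNS,
    fos_features,
    frame_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)
from droptex.matrices import GLCM_ANGLES, build_glcm, build_gldm, build_glrlm, build_glszm

from conftest import random_quantized
import oracles


class TestFOS:
    def test_constant_input(self):
        f = fos_features([5, 5, 5, 5])
        assert f["Mean"] == 5
        assert f["Variance"] == 0
        assert f["Uniformity"] == 1
        assert f["Energy"] == 100
        assert f["Entropy"] == pytest.approx(-np.log2(1 + EPS), abs=1e-12)
        assert f["Skewness"] == 0 and f["Kurtosis"] == 0

    def test_two_extremes(self):
        f = fos_features([0, 255])
        assert f["Mean"] == 127.5
        assert f["Variance"] == 16256.25
        assert f["Uniformity"] == 0.5
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(255**2 / 2))

    def test_moment_oracle(self):
        x = [1, 2, 3, 4, 5, 6, 6, 6]
        f = fos_features(x)
        o = oracles.fos_oracle(x)
        for k in f:
            assert f[k] == pytest.approx(o[k], abs=1e-12), k

    def test_shift_constant(self):
        f = fos_features([1, 2, 3], c=10.0)
        assert f["Energy"] == 11**2 + 12**2 + 13**2
        assert f["Mean"] == 2  # shift applies to Energy/RMS only


class TestGLCMFeatures:
    def test_checkerboard_hand_values(self):
        frame = (np.indices((4, 4)).sum(axis=0) % 2).astype(np.uint8)
        roi = droptex.quantize(frame, np.ones((4, 4), bool), 1)
        f = glcm_features(build_glcm(roi, angles=(0,)))
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Correlation"] == pytest.approx(-1.0)
        assert f["IDM"] == pytest.approx(0.5)
        assert f["MaximumProbability"] == pytest.approx(0.5)

    def test_constant_image(self):
        roi = droptex.quantize(np.full((4, 4), 7, np.uint8), np.ones((4, 4), bool), 1)
        f = glcm_features(build_glcm(roi))
        assert f["Contrast"] == 0
        assert f["IDM"] == pytest.approx(1.0)
        assert f["MaximumProbability"] == pytest.approx(1.0)
        assert f["Correlation"] == 1.0  # zero-variance convention

    def test_oracle_equivalence_all_angles(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            roi = random_quantized(rng, masked=False)
            m = build_glcm(roi)
            f = glcm_features(m)
            per_angle = [
                oracles.glcm_features_oracle(oracles.glcm_oracle(roi.levels, roi.n_g, 1, a))
                for a in GLCM_ANGLES
            ]
            for k in f:
                expected = np.mean([o[k] for o in per_angle])
                assert f[k] == pytest.approx(expected, abs=1e-10), k


class TestGLRLMFeatures:
    def test_row_example(self):
        frame = np.array([[1, 1, 2, 2, 2]], dtype=np.uint8)
        roi = droptex.quantize(frame, np.ones((1, 5), bool), 1)
        f = glrlm_features({0: build_glrlm(roi, 0)})
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["RunVariance"] == pytest.approx(0.25)

    def test_single_row_constant_run_entropy_zero(self):
        frame = np.full((1, 6), 4, dtype=np.uint8)
        roi = droptex.quantize(frame, np.ones((1, 6), bool), 1)
        f = glrlm_features({0: build_glrlm(roi, 0)})
        assert f["RunEntropy"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            roi = random_quantized(rng)
            mats = {a: build_glrlm(roi, a) for a in GLCM_ANGLES}
            f = glrlm_features(mats)
            per_angle = [
                oracles.glrlm_features_oracle(oracles.glrlm_oracle(roi.levels, roi.n_g, a))
                for a in GLCM_ANGLES
            ]
            for k in f:
                assert f[k] == pytest.approx(np.mean([o[k] for o in per_angle]), abs=1e-10)


class TestGLSZMFeatures:
    def test_two_zone_example(self):
        frame = np.array([[1, 1], [1, 2]], dtype=np.uint8)
        roi = droptex.quantize(frame, np.ones((2, 2), bool), 1)
        f = glszm_features(build_glszm(roi))
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["SizeZoneNonUniformity"] == pytest.approx(1.0)
        assert f["ZoneEntropy"] == pytest.approx(1.0)

    def test_single_zone(self):
        roi = droptex.quantize(np.full((3, 3), 1, np.uint8), np.ones((3, 3), bool), 1)
        f = glszm_features(build_glszm(roi))
        assert f["ZoneEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["ZoneVariance"] == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(29)
        frame = rng.integers(0, 5, (8, 8)).astype(np.uint8)
        mask = np.ones((8, 8), bool)
        a = glszm_features(build_glszm(droptex.quantize(frame, mask, 1)))
        b = glszm_features(build_glszm(droptex.quantize(np.rot90(frame).copy(), mask, 1)))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            roi = random_quantized(rng)
            f = glszm_features(build_glszm(roi))
            o = oracles.glszm_features_oracle(oracles.glszm_oracle(roi.levels, roi.n_g))
            for k in f:
                assert f[k] == pytest.approx(o[k], abs=1e-10)


class TestGLDMFeatures:
    def test_constant_3x3_hand_values(self):
        roi = droptex.quantize(np.full((3, 3), 6, np.uint8), np.ones((3, 3), bool), 1)
        f = gldm_features(build_gldm(roi))
        assert f["DependenceNonUniformity"] == pytest.approx(33 / 9)
        mu = 40 / 9
        expected_dv = (4 * (3 - mu) ** 2 + 4 * (5 - mu) ** 2 + (8 - mu) ** 2) / 9
        assert f["DependenceVariance"] == pytest.approx(expected_dv)

    def test_single_pixel_roi(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        roi = droptex.quantize(np.zeros((3, 3), np.uint8), mask, 1)
        f = gldm_features(build_gldm(roi))
        assert f["DependenceEntropy"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            roi = random_quantized(rng)
            f = gldm_features(build_gldm(roi))
            o = oracles.gldm_features_oracle(oracles.gldm_oracle(roi.levels, roi.n_g))
            for k in f:
                assert f[k] == pytest.approx(o[k], abs=1e-10)


class TestBounds:
    """Feature-range invariants over random masked images."""

    def test_bounds_random_images(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            roi = random_quantized(rng)
            frame = (roi.levels * 10).astype(np.uint8)
            feats = frame_features(frame, roi.mask)
            assert 0 < feats["fos_Uniformity"] <= 1
            n_g_fos = len(np.unique(frame[roi.mask]))
            assert 0 <= feats["fos_Entropy"] <= np.log2(n_g_fos) + 1e-9
            assert -1 - 1e-9 <= feats["glcm_Correlation"] <= 1 + 1e-9
            assert 0 < feats["glcm_IDM"] <= 1
            assert 0 < feats["glcm_MaximumProbability"] <= 1
            for k, v in feats.items():
                assert np.isfinite(v), k

    def test_angle_average_invariant_under_rotation(self):
        """Rotating 90 deg permutes per-angle values but leaves the four-angle
        averages unchanged (square mask)."""
        rng = np.random.default_rng(43)
        frame = rng.integers(0, 120, (9, 9)).astype(np.uint8)
        mask = np.ones((9, 9), bool)
        a = frame_features(frame, mask)
        b = frame_features(np.rot90(frame).copy(), mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k


class TestFeatureTable:
    def test_shape_and_columns(self, small_dataset, small_feature_table):
        cfg, _ = small_dataset
        per = small_feature_table[small_feature_table["label"] == "0x"]
        assert len(per) == cfg.n_frames
        assert small_feature_table.shape[1] == 34
        assert list(small_feature_table.columns[4:]) == list(FEATURE_COLUMNS)

    def test_deterministic(self, small_dataset):
        _, dataset = small_dataset
        s = dataset[0]
        a = droptex.extract_feature_table(s)
        b = droptex.extract_feature_table(s)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_frames_identical_rows(self):
        frame = np.random.default_rng(0).integers(0, 200, (32, 32)).astype(np.uint8)
        mask = droptex.circular_mask((32, 32))
        series = droptex.DropletSeries(
            frames=np.stack([frame, frame, frame]),
            mask=mask,
            times_norm=[0.0, 0.5, 1.0],
            stages=["initial", "middle", "final"],
            label="0x",
        )
        t = droptex.extract_feature_table(series)
        assert (t.iloc[0][list(FEATURE_COLUMNS)] == t.iloc[1][list(FEATURE_COLUMNS)]).all()

    def test_constant_frame_degenerate_row(self):
        frame = np.full((20, 20), 77, dtype=np.uint8)
        mask = droptex.circular_mask((20, 20))
        series = droptex.DropletSeries(
            frames=frame[None],
            mask=mask,
            times_norm=[0.0],
            stages=["initial"],
            label="0x",
        )
        row = droptex.extract_feature_table(series).iloc[0]
        assert row["fos_Uniformity"] == 1.0
        assert row["glcm_Contrast"] == 0.0
        assert row["glszm_ZoneEntropy"] == pytest.approx(0.0, abs=1e-12)
        assert row["gldm_DependenceEntropy"] > 0  # edge pixels vary in d
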