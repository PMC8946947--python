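"""Feature-level checks: closed forms, independent statistics, and the
178-name extraction contract."""

import numpy as np
import pytest
from scipy import stats

from ironmap.io_preproc import LabelMask, Volume
from ironmap.radiomics import (
    DiscretizedROI,
    ExtractionConfig,
    compute_gldm,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    extract_all,
    first_order_features,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    shape_features,
)
from ironmap.radiomics.firstorder import SIGNAL_BASED_FEATURES, texture_safe
from ironmap.synthetic_data import LEGEND, PhantomSpec, generate_subject

from .oracles import moments
from .test_radiomics_matrices import random_roi


def constant_roi(level: int, ng: int, shape=(3, 3, 3)) -> DiscretizedROI:
    levels = np.full(shape, level, dtype=np.int64)
    return DiscretizedROI(levels, ng, levels > 0, np.ones(3), 25.0)


class TestGLCMFeatures:
    def test_constant_roi_closed_forms(self):
        g = 3
        f = glcm_features(compute_glcm(constant_roi(g, g), delta=1))
        assert f["Autocorrelation"] == pytest.approx(g**2)
        assert f["JointAverage"] == pytest.approx(g)
        assert f["SumAverage"] == pytest.approx(2 * g)
        assert f["ClusterShade"] == pytest.approx(0.0)
        assert f["Imc2"] == 0.0 and f["MCC"] == 0.0  # single-level convention

    @pytest.mark.parametrize("seed", range(10))
    def test_imc2_and_mcc_bounded(self, seed):
        d = random_roi(seed)
        f = glcm_features(compute_glcm(d, delta=1))
        assert -1e-9 <= f["Imc2"] <= 1.0 + 1e-9
        assert -1e-9 <= f["MCC"] <= 1.0 + 1e-9

    def test_sum_average_twice_joint_average(self):
        # an identity of symmetric co-occurrence marginals
        d = random_roi(42)
        f = glcm_features(compute_glcm(d, delta=1))
        assert f["SumAverage"] == pytest.approx(2.0 * f["JointAverage"], rel=1e-9)

    def test_contrast_grows_with_distance_on_gradient(self):
        ramp = np.tile(np.arange(1, 13, dtype=np.int64)[:, None, None], (1, 8, 8))
        d = DiscretizedROI(ramp, 12, ramp > 0, np.ones(3), 25.0)
        c1 = glcm_features(compute_glcm(d, 1))["Contrast"]
        c7 = glcm_features(compute_glcm(d, 7))["Contrast"]
        assert c7 >= c1

    def test_all_angles_empty_raises(self):
        levels = np.zeros((2, 2, 2), dtype=np.int64)
        levels[0, 0, 0] = 1
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        with pytest.raises(ValueError, match="empty"):
            glcm_features(compute_glcm(d, delta=5))


class TestGLRLMFeatures:
    def test_single_run_gray_level_nonuniformity(self):
        levels = np.zeros((4, 1, 1), dtype=np.int64)
        levels[:, 0, 0] = 2
        d = DiscretizedROI(levels, 2, levels > 0, np.ones(3), 25.0)
        axial = [m for m in compute_glrlm(d) if m.angle == (1, 0, 0)]
        f = glrlm_features(axial)
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["RunEntropy"] == pytest.approx(0.0)


class TestGLSZMFeatures:
    def test_constant_roi_single_zone(self):
        d = constant_roi(1, 1, (4, 4, 4))
        f = glszm_features(compute_glszm(d))
        assert f["ZonePercentage"] == pytest.approx(1.0 / 64.0)
        assert f["LargeAreaEmphasis"] == pytest.approx(64.0**2)


class TestGLDMFeatures:
    def test_high_gray_level_emphasis_single_level(self):
        d = constant_roi(4, 4)
        f = gldm_features(compute_gldm(d))
        assert f["HighGrayLevelEmphasis"] == pytest.approx(16.0)
        assert f["LowGrayLevelEmphasis"] == pytest.approx(1.0 / 16.0)


class TestNGTDMFeatures:
    def test_constant_roi_degenerate_values(self):
        d = constant_roi(1, 1)
        f = ngtdm_features(compute_ngtdm(d, 1))
        assert f["Contrast"] == 0.0
        assert f["Busyness"] == 0.0
        assert f["Coarseness"] > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_coarseness_positive(self, seed):
        d = random_roi(seed)
        f = ngtdm_features(compute_ngtdm(d, 1))
        assert f["Coarseness"] > 0.0


class TestFirstOrder:
    def _vol_mask(self, data):
        vol = Volume(data, np.eye(4), "SWI")
        return vol, LabelMask(np.ones(data.shape, np.int32), vol, LEGEND)

    def test_constant_roi_zero_variance_entropy(self):
        vol, mask = self._vol_mask(np.full((4, 4, 4), 9.0))
        f = first_order_features(vol, mask, "putamen")
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_filter_view_excludes_signal_features(self, rng):
        vol, mask = self._vol_mask(rng.normal(100, 10, (5, 5, 5)))
        f = texture_safe(first_order_features(vol, mask, "putamen"))
        assert not SIGNAL_BASED_FEATURES & set(f)
        assert "Skewness" in f and "Entropy" in f

    def test_moments_match_independent_routines(self, rng):
        data = rng.normal(50, 12, (6, 6, 6))
        vol, mask = self._vol_mask(data)
        f = first_order_features(vol, mask, "putamen")
        x = data.ravel()
        oracle = moments(list(x))
        assert f["Skewness"] == pytest.approx(oracle["skewness"], abs=1e-9)
        assert f["Kurtosis"] == pytest.approx(oracle["kurtosis"], abs=1e-9)
        # scipy uses the same population definitions (Fisher off for kurtosis)
        assert f["Skewness"] == pytest.approx(stats.skew(x), abs=1e-12)
        assert f["Kurtosis"] == pytest.approx(stats.kurtosis(x, fisher=False), abs=1e-12)

    def test_feature_count_is_nineteen(self, rng):
        vol, mask = self._vol_mask(rng.normal(0, 1, (4, 4, 4)))
        assert len(first_order_features(vol, mask, "putamen")) == 19


class TestShape:
    def _mask_from(self, roi, spacing=(1.0, 1.0, 1.0)):
        affine = np.diag([*spacing, 1.0])
        grid = Volume(np.zeros(roi.shape), affine)
        return LabelMask(roi.astype(np.int32), grid, {1: "putamen"})

    def test_single_voxel_volume(self):
        roi = np.zeros((5, 5, 5), dtype=np.int32)
        roi[2, 2, 2] = 1
        f3, f2 = shape_features(self._mask_from(roi), "putamen")
        assert f3["VoxelVolume"] == pytest.approx(1.0)
        assert len(f3) == 16 and len(f2) == 10

    def test_box_voxel_volume(self):
        roi = np.zeros((10, 10, 10), dtype=np.int32)
        roi[1:5, 1:6, 1:7] = 1  # 4 x 5 x 6 box
        f3, _ = shape_features(self._mask_from(roi), "putamen")
        assert f3["VoxelVolume"] == pytest.approx(120.0)

    def test_ball_sphericity_near_one(self):
        r = 9
        n = 2 * r + 5
        idx = np.indices((n, n, n), dtype=float) - (n - 1) / 2
        ball = (idx**2).sum(axis=0) <= r * r
        f3, f2 = shape_features(self._mask_from(ball), "putamen")
        assert f3["Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert f2["Sphericity"] == pytest.approx(1.0, abs=0.08)
        assert f3["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.1)

    def test_anisotropic_spacing_respected(self):
        roi = np.zeros((6, 6, 6), dtype=np.int32)
        roi[1:3, 1:3, 1:3] = 1
        f3, _ = shape_features(self._mask_from(roi, spacing=(0.75, 0.75, 2.0)), "putamen")
        assert f3["VoxelVolume"] == pytest.approx(8 * 0.75 * 0.75 * 2.0)


class TestExtractAll:
    @pytest.fixture(scope="class")
    def subject(self):
        return generate_subject(PhantomSpec(class_name="MSA-P", seed=9))

    def test_contract_178_unique_names(self, subject):
        fv = extract_all(subject.swi, subject.truth, "putamen")
        assert len(fv) == 178
        assert len(set(fv.names())) == 178

    def test_family_counts(self, subject):
        fv = extract_all(subject.swi, subject.truth, "putamen")
        counts = {}
        for name in fv.names():
            counts[name.split("_")[0]] = counts.get(name.split("_")[0], 0) + 1
        assert counts == {
            "firstorder": 19, "shape": 16, "shape2D": 10,
            "glcm": 72, "glrlm": 16, "glszm": 16, "ngtdm": 15, "gldm": 14,
        }

    def test_glcm_names_are_24_bases_by_3_distances(self, subject):
        fv = extract_all(subject.swi, subject.truth, "putamen")
        glcm = [n for n in fv.names() if n.startswith("glcm_")]
        bases = {n[5:-1] for n in glcm}  # suffix is exactly one distance digit
        for base in bases:
            for delta in (1, 4, 7):
                assert f"glcm_{base}{delta}" in fv.values
        assert len(bases) == 24

    def test_deterministic(self, subject):
        a = extract_all(subject.swi, subject.truth, "putamen")
        b = extract_all(subject.swi, subject.truth, "putamen")
        assert a.values == b.values

    def test_small_roi_distance_flagged_not_dropped(self):
        data = np.random.default_rng(0).normal(100, 10, (8, 8, 8))
        vol = Volume(data, np.eye(4), "SWI")
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[3:5, 3:5, 3:5] = 1  # 2-cube: no pairs at distance 4 or 7
        mask = LabelMask(labels, vol, LEGEND)
        with pytest.warns(UserWarning, match="distance"):
            fv = extract_all(vol, mask, "putamen")
        assert "glcm_distance_4_empty" in fv.flags
        assert "glcm_distance_7_empty" in fv.flags
        assert len(fv) == 178

    def test_texture_safe_drops_nine_signal_features(self, subject):
        fv = extract_all(subject.swi, subject.truth, "putamen")
        assert len(fv.texture_safe()) == 178 - 9

    def test_translation_invariance_of_texture_families(self, subject):
        """Rigid whole-voxel shifts leave every texture feature unchanged."""
        swi, truth = subject.swi, subject.truth
        shifted_data = np.roll(swi.data, (2, 1, 3), axis=(0, 1, 2))
        shifted_labels = np.roll(truth.labels, (2, 1, 3), axis=(0, 1, 2))
        swi2 = swi.with_data(shifted_data)
        truth2 = LabelMask(shifted_labels, swi2, truth.legend)
        a = extract_all(swi, truth, "putamen")
        b = extract_all(swi2, truth2, "putamen")
        for name in a.names():
            if name.split("_")[0] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
                assert a[name] == pytest.approx(b[name], rel=1e-9), name
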