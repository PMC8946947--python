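"""Texture matrices vs exhaustive brute-force enumeration, plus closed forms."""

import numpy as np
import pytest

from ironmap.io_preproc import LabelMask, Volume
from ironmap.radiomics import (
    ANGLES_13,
    DiscretizedROI,
    compute_gldm,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
    discretize,
)
from ironmap.synthetic_data import LEGEND

from . import oracles


def random_roi(seed: int) -> DiscretizedROI:
    """A seeded random ROI up to 6 voxels a side with a random level count."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 7, size=3))
    ng = int(rng.integers(2, 6))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int64)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask[0, 0, 0] = True
    levels[~mask] = 0
    ng_eff = int(levels.max()) if levels.max() > 0 else 1
    if levels.max() == 0:
        levels[0, 0, 0] = 1
        mask[0, 0, 0] = True
    return DiscretizedROI(levels, ng_eff, levels > 0, np.ones(3), 25.0)


SEEDS = list(range(50))


class TestDiscretize:
    def _vol_mask(self, data):
        vol = Volume(data, np.eye(4), "SWI")
        labels = np.full(data.shape, 1, dtype=np.int32)
        return vol, LabelMask(labels, vol, LEGEND)

    def test_constant_roi_single_level(self):
        vol, mask = self._vol_mask(np.full((3, 3, 3), 42.0))
        d = discretize(vol, mask, "putamen")
        assert d.ng == 1
        assert set(d.levels[d.mask]) == {1}

    def test_floor_rule_on_known_values(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [0.0, 25.0, 50.0]
        vol, mask = self._vol_mask(data)
        d = discretize(vol, mask, "putamen", bin_width=25.0)
        assert sorted(d.levels[d.mask]) == [1, 2, 3]

    def test_histogram_matches_independent_binning(self, rng):
        data = rng.normal(100, 30, (6, 6, 6))
        vol, mask = self._vol_mask(data)
        d = discretize(vol, mask, "putamen", bin_width=10.0)
        expected = np.floor((data - data.min()) / 10.0).astype(int) + 1
        got = np.bincount(d.levels[d.mask])
        want = np.bincount(expected.ravel())
        np.testing.assert_array_equal(got, want)

    def test_nonpositive_bin_width_rejected(self, rng):
        vol, mask = self._vol_mask(rng.normal(0, 1, (3, 3, 3)))
        with pytest.raises(ValueError, match="positive"):
            discretize(vol, mask, "putamen", bin_width=0.0)


class TestGLCM:
    def test_constant_cube_single_entry(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        for m in compute_glcm(d, delta=1):
            assert m.values.shape == (1, 1)
            assert m.values[0, 0] == pytest.approx(1.0)

    def test_two_voxel_line_symmetrized(self):
        levels = np.zeros((2, 1, 1), dtype=np.int64)
        levels[:, 0, 0] = [1, 2]
        d = DiscretizedROI(levels, 2, levels > 0, np.ones(3), 25.0)
        mats = compute_glcm(d, delta=1)
        axial = [m for m in mats if m.angle == (1, 0, 0)][0]
        assert axial.values[0, 1] == pytest.approx(0.5)
        assert axial.values[1, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", SEEDS)
    @pytest.mark.parametrize("delta", [1, 4, 7])
    def test_matches_pair_enumeration_oracle(self, seed, delta):
        d = random_roi(seed)
        for m in compute_glcm(d, delta=delta, normalize=False):
            expected = oracles.glcm_pairs(d.levels, d.ng, delta, m.angle)
            np.testing.assert_array_equal(m.values, expected)

    def test_normalized_unit_mass_and_symmetry(self):
        d = random_roi(123)
        for m in compute_glcm(d, delta=1):
            if not m.empty:
                assert m.values.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(m.values, m.values.T)


class TestGLRLM:
    def test_single_straight_run(self):
        levels = np.zeros((5, 1, 1), dtype=np.int64)
        levels[:, 0, 0] = 2
        d = DiscretizedROI(levels, 2, levels > 0, np.ones(3), 25.0)
        axial = [m for m in compute_glrlm(d) if m.angle == (1, 0, 0)][0]
        assert axial.values[1, 4] == 1.0  # one run of level 2, length 5
        assert axial.values.sum() == 1.0

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_run_enumeration_oracle(self, seed):
        d = random_roi(seed)
        for m in compute_glrlm(d):
            expected = oracles.glrlm_runs(d.levels, d.ng, m.angle)
            trimmed = m.values[:, : expected.shape[1]]
            assert m.values[:, expected.shape[1]:].sum() == 0
            np.testing.assert_array_equal(trimmed, expected)


class TestGLSZM:
    def test_constant_roi_single_zone(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        m = compute_glszm(d)
        assert m.values[0, 63] == 1.0
        assert m.values.sum() == 1.0

    def test_two_separated_blobs(self):
        levels = np.zeros((7, 3, 3), dtype=np.int64)
        levels[0:2] = 1
        levels[5:7] = 1
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        m = compute_glszm(d)
        assert m.values[0, 17] == 2.0  # two zones of 18 voxels each

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_flood_fill_oracle(self, seed):
        d = random_roi(seed)
        got = compute_glszm(d).values
        expected = oracles.glszm_zones(d.levels, d.ng)
        assert got.shape == expected.shape
        np.testing.assert_array_equal(got, expected)


class TestGLDM:
    def test_constant_cube_center_dependence_26(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        m = compute_gldm(d, alpha=0)
        assert m.values[0, 26] == 1.0  # exactly the center voxel

    def test_single_voxel_dependence_zero(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        levels[1, 1, 1] = 1
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        m = compute_gldm(d, alpha=0)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1.0

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_neighborhood_scan_oracle(self, seed):
        d = random_roi(seed)
        got = compute_gldm(d, alpha=0).values
        expected = oracles.gldm_counts(d.levels, d.ng, alpha=0)
        assert got.shape == expected.shape
        np.testing.assert_array_equal(got, expected)


class TestNGTDM:
    def test_constant_roi_all_s_zero(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        d = DiscretizedROI(levels, 1, levels > 0, np.ones(3), 25.0)
        m = compute_ngtdm(d, delta=1)
        assert m.values[0, 2] == pytest.approx(0.0)

    def test_1d_hand_enumeration(self):
        levels = np.zeros((3, 1, 1), dtype=np.int64)
        levels[:, 0, 0] = [1, 3, 1]
        d = DiscretizedROI(levels, 3, levels > 0, np.ones(3), 25.0)
        table = compute_ngtdm(d, delta=1).values
        # voxel 0: neighbor mean 3 -> |1-3| = 2; voxel 2 likewise
        # voxel 1: neighbor mean 1 -> |3-1| = 2
        assert table[0, 2] == pytest.approx(4.0)
        assert table[2, 2] == pytest.approx(2.0)
        assert table[0, 0] == 2 and table[2, 0] == 1

    @pytest.mark.parametrize("seed", SEEDS)
    @pytest.mark.parametrize("delta", [1, 4, 7])
    def test_matches_offset_enumeration_oracle(self, seed, delta):
        d = random_roi(seed)
        got = compute_ngtdm(d, delta=delta).values
        expected = oracles.ngtdm_table(d.levels, d.ng, delta)
        np.testing.assert_allclose(got, expected, atol=1e-8)


class TestTranslationInvariance:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_all_matrices_unchanged_under_voxel_shift(self, seed):
        d = random_roi(seed)
        padded = np.zeros(tuple(s + 4 for s in d.levels.shape), dtype=np.int64)
        padded[2:-2, 2:-2, 2:-2] = d.levels
        shifted = DiscretizedROI(padded, d.ng, padded > 0, d.spacing, 25.0)
        for delta in (1, 4):
            for a, b in zip(compute_glcm(d, delta), compute_glcm(shifted, delta)):
                np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        got = compute_glszm(shifted).values
        np.testing.assert_array_equal(compute_glszm(d).values, got)
        np.testing.assert_array_equal(
            compute_gldm(d).values, compute_gldm(shifted).values
        )
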