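"""Texture matrices and their features, against brute-force oracles."""

import numpy as np
import pytest

from radrobust.features import (
    DIRECTIONS_3D,
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    discretize,
    glc_matrix,
    glcm_features,
    glrl_matrix,
    glrlm_features,
    texture_features,
)

from oracles import glcm_brute, glcm_features_brute, glrlm_brute, glrlm_features_brute


def _disc(levels, mask=None):
    """Wrap an integer level grid as a DiscretizedVolume via intensities."""
    levels = np.asarray(levels, dtype=float)
    if mask is None:
        mask = np.ones(levels.shape, bool)
    return discretize(levels, mask, bin_width=1.0)


class TestDirectionSet:
    def test_thirteen_directions_nonredundant(self):
        assert len(DIRECTIONS_3D) == 13
        seen = {tuple(d) for d in DIRECTIONS_3D}
        assert len(seen) == 13
        for d in DIRECTIONS_3D:
            assert tuple(-d) not in seen
            assert np.abs(d).max() == 1

    def test_union_with_negations_is_26_neighborhood(self):
        full = {tuple(d) for d in DIRECTIONS_3D} | {tuple(-d) for d in DIRECTIONS_3D}
        expected = {
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        }
        assert full == expected


class TestGLCM:
    def test_two_level_plane_pairs(self):
        levels = np.array([[[1, 1], [2, 2]]])  # shape (1, 2, 2); rows differ on y
        d = _disc(levels)
        P = glc_matrix(d, np.array([0, 1, 0]))
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_constant_grid_single_diagonal_entry(self):
        d = _disc(np.full((3, 3, 3), 5.0))
        P = glc_matrix(d, np.array([1, 0, 0]))
        assert P.shape == (1, 1) and P[0, 0] == 1.0

    def test_masked_endpoint_excluded(self):
        levels = np.array([[[1, 2, 1]]], dtype=float)
        mask = np.array([[[True, True, False]]])
        d = _disc(levels, mask)
        P = glc_matrix(d, np.array([0, 0, 1]))
        # only the (1,2) pair remains
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)

    def test_features_on_off_diagonal_example(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(P)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)
        assert f["maximum_probability"] == pytest.approx(0.5)

    def test_features_single_diagonal_entry(self):
        P = np.zeros((3, 3))
        P[1, 1] = 1.0
        f = glcm_features(P)
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert np.isnan(f["correlation"])  # zero marginal variance

    def test_probability_mass_and_symmetry_random(self, rng):
        for _ in range(10):
            vol = rng.integers(0, 4, size=(5, 5, 5)).astype(float)
            mask = rng.random((5, 5, 5)) > 0.3
            if mask.sum() < 4:
                continue
            d = _disc(vol, mask)
            for direction in DIRECTIONS_3D:
                P = glc_matrix(d, direction)
                if P is None:
                    continue
                assert P.sum() == pytest.approx(1.0)
                assert np.allclose(P, P.T)


class TestGLRLM:
    def test_single_run(self):
        from radrobust.features import DiscretizedVolume

        levels = np.full((1, 1, 4), 3, dtype=np.int64)
        d = DiscretizedVolume(levels=levels, mask=np.ones(levels.shape, bool),
                              bin_width=1.0, n_levels=3, min_intensity=0.0)
        R = glrl_matrix(d, np.array([0, 0, 1]))
        assert R.shape == (3, 4)
        assert R[2, 3] == 1 and R.sum() == 1

    def test_alternating_levels_unit_runs(self):
        levels = np.array([[[1, 2, 1, 2]]], dtype=float)
        d = _disc(levels)
        R = glrl_matrix(d, np.array([0, 0, 1]))
        assert R.shape[1] == 1 and R.sum() == 4

    def test_voxel_conservation_random(self, rng):
        for _ in range(10):
            vol = rng.integers(0, 4, size=(6, 6, 6)).astype(float)
            mask = rng.random((6, 6, 6)) > 0.4
            if not mask.any():
                continue
            d = _disc(vol, mask)
            for direction in DIRECTIONS_3D:
                R = glrl_matrix(d, direction)
                lens = np.arange(1, R.shape[1] + 1)
                assert (R * lens).sum() == mask.sum()

    def test_features_single_run_example(self):
        R = np.zeros((3, 4))
        R[2, 3] = 1.0  # one run: level 3, length 4
        f = glrlm_features(R, n_voxels=4)
        assert f["short_run_emphasis"] == pytest.approx(1 / 16)
        assert f["long_run_emphasis"] == pytest.approx(16.0)
        assert f["run_percentage"] == pytest.approx(0.25)

    def test_unit_runs_degenerate(self):
        R = np.array([[2.0], [3.0]])
        f = glrlm_features(R, n_voxels=5)
        assert f["short_run_emphasis"] == 1.0
        assert f["long_run_emphasis"] == 1.0

    def test_sre_lre_bracket_unity(self, rng):
        # Jensen-type ordering whenever some run is longer than 1
        for _ in range(20):
            R = rng.integers(0, 5, size=(3, 4)).astype(float)
            if R.sum() == 0 or R[:, 1:].sum() == 0:
                continue
            f = glrlm_features(R, n_voxels=int((R * np.arange(1, 5)).sum()))
            assert f["short_run_emphasis"] < 1.0 < f["long_run_emphasis"]


class TestBruteForceEquality:
    """Vectorized matrices and features vs naive loop oracles."""

    @pytest.mark.parametrize("seed", range(5))
    def test_matrices_and_features_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.integers(0, 4, size=(6, 6, 6)).astype(float)
        mask = rng.random((6, 6, 6)) > 0.25
        mask[3, 3, 3] = True
        d = _disc(vol, mask)
        n_voxels = int(mask.sum())
        for direction in DIRECTIONS_3D:
            P = glc_matrix(d, direction)
            P_ref = glcm_brute(d.levels, mask, direction)
            assert np.allclose(P, P_ref, rtol=1e-12, atol=1e-15)
            ours = glcm_features(P)
            ref = glcm_features_brute(P_ref)
            for name in GLCM_FEATURE_NAMES:
                if np.isnan(ref[name]):
                    assert np.isnan(ours[name])
                else:
                    assert ours[name] == pytest.approx(ref[name], rel=1e-10, abs=1e-12)
            R = glrl_matrix(d, direction)
            R_ref = glrlm_brute(d.levels, mask, direction)
            assert np.array_equal(R, R_ref)
            ours_r = glrlm_features(R, n_voxels)
            ref_r = glrlm_features_brute(R_ref, n_voxels)
            for name in GLRLM_FEATURE_NAMES:
                assert ours_r[name] == pytest.approx(ref_r[name], rel=1e-10)

    def test_direction_average_equals_pooled_per_direction_oracle(self):
        rng = np.random.default_rng(99)
        vol = rng.integers(0, 4, size=(6, 6, 6)).astype(float)
        mask = np.ones((6, 6, 6), bool)
        d = _disc(vol, mask)
        out = texture_features(d)
        for fam, names, mat_fn, feat_fn in [
            ("glcm", GLCM_FEATURE_NAMES, glcm_brute,
             lambda M: glcm_features_brute(M)),
            ("glrlm", GLRLM_FEATURE_NAMES, glrlm_brute,
             lambda M: glrlm_features_brute(M, int(mask.sum()))),
        ]:
            per_dir = [feat_fn(mat_fn(d.levels, mask, direction))
                       for direction in DIRECTIONS_3D]
            for name in names:
                vals = [p[name] for p in per_dir if not np.isnan(p[name])]
                assert out[f"{fam}_{name}"] == pytest.approx(np.mean(vals), rel=1e-10)

    def test_isotropic_constant_texture_mean_equals_single_direction(self):
        d = _disc(np.full((4, 4, 4), 2.0))
        out = texture_features(d)
        single = glcm_features(glc_matrix(d, DIRECTIONS_3D[0]))
        assert out["glcm_energy"] == pytest.approx(single["energy"])
        assert out["glcm_entropy"] == pytest.approx(single["entropy"])
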