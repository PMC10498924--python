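"""Texture features vs. brute-force enumeration oracles on tiny grids."""

import numpy as np
import pytest

from petrad.radiomics import (
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glszm_features,
    glszm_matrix,
    run_lengths,
    unique_directions_3d,
)

ALL_26 = [(dz, dy, dx)
          for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
          if (dz, dy, dx) != (0, 0, 0)]


def random_levels(seed, max_side=6, n_levels=4):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    out = np.where(mask, levels, 0)
    return out


# -- oracles ---------------------------------------------------------------


def glcm_oracle(levels, direction, n_levels):
    """Count co-occurring pairs voxel by voxel (both directions)."""
    mat = np.zeros((n_levels, n_levels))
    for idx in np.ndindex(levels.shape):
        a = levels[idx]
        if a == 0:
            continue
        for sign in (1, -1):
            nb = tuple(i + sign * d for i, d in zip(idx, direction))
            if all(0 <= n < s for n, s in zip(nb, levels.shape)):
                b = levels[nb]
                if b > 0:
                    mat[a - 1, b - 1] += 1
    total = mat.sum()
    return mat / total if total else mat


def zones_oracle(levels):
    """Flood-fill (BFS, 26-connected) zone enumeration."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    for start in np.ndindex(levels.shape):
        if levels[start] == 0 or visited[start]:
            continue
        g = levels[start]
        queue = [start]
        visited[start] = True
        size = 0
        while queue:
            cur = queue.pop()
            size += 1
            for d in ALL_26:
                nb = tuple(i + o for i, o in zip(cur, d))
                if all(0 <= n < s for n, s in zip(nb, levels.shape)) \
                        and not visited[nb] and levels[nb] == g:
                    visited[nb] = True
                    queue.append(nb)
        zones.append((int(g), size))
    return zones


def runs_oracle(levels, direction):
    """Enumerate maximal runs by walking every line."""
    runs = []
    d = np.asarray(direction)
    for start in np.ndindex(levels.shape):
        g = levels[start]
        if g == 0:
            continue
        prev = tuple(np.asarray(start) - d)
        if all(0 <= p < s for p, s in zip(prev, levels.shape)) and levels[prev] == g:
            continue  # not a run start
        length = 0
        pos = np.asarray(start)
        while all(0 <= p < s for p, s in zip(pos, levels.shape)) \
                and levels[tuple(pos)] == g:
            length += 1
            pos = pos + d
        runs.append((int(g), length))
    return runs


# -- GLCM ------------------------------------------------------------------


class TestGlcm:
    def test_thirteen_unique_directions(self):
        dirs = unique_directions_3d()
        assert len(dirs) == 13
        assert len({d for d in dirs} | {tuple(-x for x in d) for d in dirs}) == 26

    def test_constant_region(self):
        levels = np.full((3, 3, 3), 2, dtype=np.int64)
        f = glcm_features(levels)
        assert f["joint_average"] == pytest.approx(2.0)
        assert f["cluster_shade"] == pytest.approx(0.0)

    def test_hand_built_two_level_grid_matches_oracle(self):
        levels = np.array([[[1, 2, 1], [2, 1, 2], [1, 1, 2]]])
        for d in unique_directions_3d():
            got = glcm_matrix(levels, d, 2)
            want = glcm_oracle(levels, d, 2)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_sum_average_is_twice_joint_average(self):
        for seed in range(10):
            levels = random_levels(seed)
            f = glcm_features(levels)
            assert f["sum_average"] == pytest.approx(2 * f["joint_average"])

    @pytest.mark.parametrize("seed", range(25))
    def test_matrix_matches_oracle_on_random_grids(self, seed):
        levels = random_levels(seed)
        n = max(int(levels.max()), 1)
        for d in unique_directions_3d():
            np.testing.assert_allclose(glcm_matrix(levels, d, n),
                                       glcm_oracle(levels, d, n), atol=1e-12)

    def test_single_voxel_mask_rejected(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        levels[1, 1, 1] = 1
        with pytest.raises(ValueError):
            glcm_features(levels)


# -- GLSZM -----------------------------------------------------------------


class TestGlszm:
    def test_constant_region_single_zone(self):
        levels = np.full((3, 3, 3), 1, dtype=np.int64)
        f = glszm_features(levels)
        assert f["gray_level_nonuniformity_normalized"] == pytest.approx(1.0)
        assert f["small_area_low_gray_level_emphasis"] == pytest.approx(1 / 27 ** 2)

    def test_checkerboard_all_zones_size_one(self):
        z, y, x = np.indices((4, 4, 1))
        levels = ((z + y + x) % 2 + 1).astype(np.int64)
        # 26-connectivity merges diagonal same-level voxels, so make levels
        # distinct per voxel instead for the size-1 claim:
        levels = np.arange(1, 17, dtype=np.int64).reshape(4, 4, 1)
        zones = glszm_matrix(levels)
        assert all(s == 1 for (_g, s) in zones)
        oracle = zones_oracle(levels)
        assert sum(zones.values()) == len(oracle)
        f = glszm_features(levels)
        manual = np.mean([1.0 / g ** 2 for (g, _s) in zones])
        assert f["small_area_low_gray_level_emphasis"] == pytest.approx(manual)

    @pytest.mark.parametrize("seed", range(25))
    def test_zone_counts_match_flood_fill_oracle(self, seed):
        levels = random_levels(seed)
        got = glszm_matrix(levels)
        oracle = zones_oracle(levels)
        assert sum(got.values()) == len(oracle)
        from collections import Counter
        assert Counter({k: v for k, v in got.items()}) == Counter(oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_features_match_oracle_formulas(self, seed):
        levels = random_levels(seed + 100)
        oracle = zones_oracle(levels)
        n_z = len(oracle)
        salgle = np.mean([1.0 / (g ** 2 * s ** 2) for g, s in oracle])
        per_level = {}
        for g, _s in oracle:
            per_level[g] = per_level.get(g, 0) + 1
        glnn = sum(v ** 2 for v in per_level.values()) / n_z ** 2
        f = glszm_features(levels)
        assert f["small_area_low_gray_level_emphasis"] == pytest.approx(salgle)
        assert f["gray_level_nonuniformity_normalized"] == pytest.approx(glnn)


# -- GLRLM -----------------------------------------------------------------


class TestGlrlm:
    def test_single_line_single_run(self):
        levels = np.zeros((1, 1, 4), dtype=np.int64)
        levels[0, 0, :] = 3
        runs = run_lengths(levels, (0, 0, 1))
        assert runs == {(3, 4): 1}
        assert glrlm_features(levels)["high_gray_level_run_emphasis"] == \
            pytest.approx(9.0)

    def test_alternating_levels_all_runs_length_one(self):
        levels = np.array([[[1, 2, 1, 2, 1]]], dtype=np.int64)
        runs = run_lengths(levels, (0, 0, 1))
        assert all(r == 1 for (_g, r) in runs)
        # HGLRE along that direction = mean of g^2 over runs
        hglre = sum(n * g ** 2 for (g, _r), n in runs.items()) / sum(runs.values())
        assert hglre == pytest.approx((3 * 1 + 2 * 4) / 5)

    @pytest.mark.parametrize("seed", range(25))
    def test_runs_match_walking_oracle(self, seed):
        levels = random_levels(seed)
        for d in unique_directions_3d():
            got = run_lengths(levels, d)
            from collections import Counter
            assert Counter(got) == Counter(runs_oracle(levels, d))

    def test_gray_level_relabeling_scales_hglre(self):
        levels = np.array([[[1, 1, 2, 2]]], dtype=np.int64)
        doubled = levels * 2
        f1 = glrlm_features(levels)["high_gray_level_run_emphasis"]
        f2 = glrlm_features(doubled)["high_gray_level_run_emphasis"]
        assert f2 == pytest.approx(4 * f1)
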