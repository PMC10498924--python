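"""Gray-level co-occurrence, size-zone and run-length texture features.

All matrices are built from a discretized volume (levels 1..G inside the
mask, 0 outside). Directional matrices (GLCM, GLRLM) use the 13 unique
3D offsets at distance 1 and features are averaged over directions;
directions contributing no pairs/runs are skipped.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def unique_directions_3d() -> list[tuple[int, int, int]]:
    """The 13 offsets covering all 26-neighbor axes once."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                if d > (0, 0, 0):  # lexicographic sign canonicalization
                    dirs.append(d)
    assert len(dirs) == 13
    return dirs


def _shifted_pairs(levels: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """In-mask gray-level pairs (a, b) at the given offset."""
    sl_from, sl_to = [], []
    for d, size in zip(direction, levels.shape):
        if d == 0:
            sl_from.append(slice(None))
            sl_to.append(slice(None))
        elif d > 0:
            sl_from.append(slice(0, size - d))
            sl_to.append(slice(d, size))
        else:
            sl_from.append(slice(-d, size))
            sl_to.append(slice(0, size + d))
    a = levels[tuple(sl_from)]
    b = levels[tuple(sl_to)]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm_matrix(levels: np.ndarray, direction, n_levels: int | None = None) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix for one direction."""
    if n_levels is None:
        n_levels = int(levels.max())
    a, b = _shifted_pairs(levels, direction)
    mat = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(mat, (a - 1, b - 1), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    g = np.arange(1, p.shape[0] + 1, dtype=np.float64)
    i = g[:, None]
    j = g[None, :]
    joint_average = float((i * p).sum())
    sum_average = float(((i + j) * p).sum())
    mu_x = float((i * p).sum())
    mu_y = float((j * p).sum())
    cluster_shade = float((((i + j - mu_x - mu_y) ** 3) * p).sum())
    return {"joint_average": joint_average, "sum_average": sum_average,
            "cluster_shade": cluster_shade}


def glcm_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """joint_average, sum_average, cluster_shade averaged over 13 directions."""
    if np.count_nonzero(levels) < 2:
        raise ValueError("need at least two in-mask voxels")
    if n_levels is None:
        n_levels = int(levels.max())
    per_dir = []
    for d in unique_directions_3d():
        p = glcm_matrix(levels, d, n_levels)
        if p.sum() > 0:
            per_dir.append(_glcm_single(p))
    if not per_dir:
        # isolated voxels only: fall back to degenerate single-level values
        lvl = float(levels[levels > 0].mean())
        return {"joint_average": lvl, "sum_average": 2 * lvl, "cluster_shade": 0.0}
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_matrix(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(gray level, zone size): n} via 26-connected components."""
    structure = np.ones((3, 3, 3), dtype=int)
    zones: dict[tuple[int, int], int] = {}
    for g in np.unique(levels[levels > 0]):
        labeled, n = ndimage.label(levels == g, structure=structure)
        if n == 0:
            continue
        sizes = ndimage.sum(levels == g, labeled, index=np.arange(1, n + 1)).astype(int)
        for s in sizes:
            zones[(int(g), int(s))] = zones.get((int(g), int(s)), 0) + 1
    return zones


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    """small_area_low_gray_level_emphasis and gray_level_nonuniformity_normalized."""
    zones = glszm_matrix(levels)
    if not zones:
        raise ValueError("mask is empty")
    n_z = sum(zones.values())
    salgle = sum(n / (g ** 2 * s ** 2) for (g, s), n in zones.items()) / n_z
    per_level: dict[int, int] = {}
    for (g, _s), n in zones.items():
        per_level[g] = per_level.get(g, 0) + n
    glnn = sum(n ** 2 for n in per_level.values()) / n_z ** 2
    return {"small_area_low_gray_level_emphasis": float(salgle),
            "gray_level_nonuniformity_normalized": float(glnn)}


def run_lengths(levels: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Maximal constant-level runs {(gray level, run length): count}."""
    shape = levels.shape
    d = np.asarray(direction)
    in_mask = levels > 0
    prev_differs = np.ones(shape, dtype=bool)
    sl_cur, sl_prev = [], []
    for delta, size in zip(direction, shape):
        if delta == 0:
            sl_cur.append(slice(None))
            sl_prev.append(slice(None))
        elif delta > 0:
            sl_cur.append(slice(delta, size))
            sl_prev.append(slice(0, size - delta))
        else:
            sl_cur.append(slice(0, size + delta))
            sl_prev.append(slice(-delta, size))
    region = prev_differs[tuple(sl_cur)]
    region[:] = levels[tuple(sl_cur)] != levels[tuple(sl_prev)]
    starts = np.argwhere(in_mask & prev_differs)
    runs: dict[tuple[int, int], int] = {}
    for start in starts:
        g = levels[tuple(start)]
        length = 1
        pos = start + d
        while (np.all(pos >= 0) and np.all(pos < shape)
               and levels[tuple(pos)] == g):
            length += 1
            pos = pos + d
        key = (int(g), int(length))
        runs[key] = runs.get(key, 0) + 1
    return runs


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    """high_gray_level_run_emphasis averaged over 13 directions."""
    if not (levels > 0).any():
        raise ValueError("mask is empty")
    vals = []
    for d in unique_directions_3d():
        runs = run_lengths(levels, d)
        n_r = sum(runs.values())
        if n_r == 0:
            continue
        hglre = sum(n * g ** 2 for (g, _r), n in runs.items()) / n_r
        vals.append(hglre)
    return {"high_gray_level_run_emphasis": float(np.mean(vals))}
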