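"""3D local binary pattern histogram features.

Each in-mask voxel is assigned a binary code by comparing spherically
sampled neighbor intensities (trilinear interpolation, edge replication at
the volume border) against the center value; ties (neighbor == center)
count as 1. Features are the normalized in-mask histogram of codes, named
by bin index (``lbp_000`` ...).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


def sphere_sample_points(n_points: int, radius: float) -> np.ndarray:
    """Deterministic Fibonacci-spiral points on a sphere of given radius."""
    i = np.arange(n_points, dtype=np.float64)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    theta = golden * i
    r_xy = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    pts = np.stack([z, r_xy * np.cos(theta), r_xy * np.sin(theta)], axis=1)
    return pts * radius


def lbp3d_codes(volume: np.ndarray, mask: np.ndarray,
                n_points: int = 8, radius: float = 1.0) -> np.ndarray:
    """Per-voxel LBP code for every in-mask voxel (flat array)."""
    if radius < 1.0:
        raise ValueError("radius must be at least one voxel")
    volume = np.asarray(volume, dtype=np.float64)
    mask_b = np.asarray(mask).astype(bool)
    if not mask_b.any():
        raise ValueError("mask is empty")
    centers = np.argwhere(mask_b).astype(np.float64)  # (M, 3)
    offsets = sphere_sample_points(n_points, radius)   # (P, 3)
    border = (centers.min(axis=0) < radius).any() or \
        (centers.max(axis=0) > np.asarray(volume.shape) - 1 - radius).any()
    if border:
        logger.info("mask touches border: neighbors sampled with edge replication")
    codes = np.zeros(centers.shape[0], dtype=np.int64)
    center_vals = volume[mask_b]
    # interpolation of a constant neighborhood can land 1 ulp below the
    # center value; the tie rule (equal counts as 1) needs a tolerance
    tol = 1e-9 * np.maximum(np.abs(center_vals), 1.0)
    for bit, off in enumerate(offsets):
        coords = (centers + off).T  # (3, M)
        neigh = ndimage.map_coordinates(volume, coords, order=1, mode="nearest")
        codes |= (neigh >= center_vals - tol).astype(np.int64) << bit
    return codes


def lbp3d_features(volume: np.ndarray, mask: np.ndarray,
                   n_points: int = 8, radius: float = 1.0) -> dict[str, float]:
    """Normalized histogram over the 2**n_points codes; sums to 1."""
    codes = lbp3d_codes(volume, mask, n_points=n_points, radius=radius)
    n_bins = 2 ** n_points
    hist = np.bincount(codes, minlength=n_bins).astype(np.float64)
    hist /= hist.sum()
    width = len(str(n_bins - 1))
    return {f"lbp_{i:0{width}d}": float(hist[i]) for i in range(n_bins)}
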