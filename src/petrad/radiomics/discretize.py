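"""Gray-level discretization of in-mask intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiscretizationSpec:
    """Either a fixed number of bins or a fixed bin width, per modality."""

    mode: str = "fixed_bin_count"   # or "fixed_bin_width"
    bins: int = 32
    bin_width: float = 1.0

    def __post_init__(self):
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def tag(self) -> str:
        if self.mode == "fixed_bin_count":
            return f"fbn{self.bins}"
        return f"fbw{self.bin_width:g}"


def discretize(volume: np.ndarray, mask: np.ndarray,
               spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Map in-mask intensities to gray levels 1..G; out-of-mask voxels are 0.

    Fixed bin count: G equal-width bins spanning the in-mask range (a
    constant region maps to level 1). Fixed bin width: level =
    floor((x - min)/w) + 1.
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask_b = np.asarray(mask).astype(bool)
    if not mask_b.any():
        raise ValueError("mask is empty")
    vals = volume[mask_b]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(volume.shape, dtype=np.int64)
    if spec.mode == "fixed_bin_count":
        if hi == lo:
            levels = np.ones(vals.shape, dtype=np.int64)
        else:
            levels = np.floor((vals - lo) / (hi - lo) * spec.bins).astype(np.int64) + 1
            levels[levels > spec.bins] = spec.bins
    else:
        levels = np.floor((vals - lo) / spec.bin_width).astype(np.int64) + 1
    out[mask_b] = levels
    return out
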