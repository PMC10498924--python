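"""CT windowing, PET scaling, VOI cropping and standard PET parameters.

The PET parameters quantify tracer uptake within the primary tumor mask:

* ``suv_peak`` — maximum mean SUV over a 1 cm^3 sphere centered on a voxel
  inside the tumor mask (the sphere itself may extend beyond the mask).
* ``mtv`` — metabolic tumor volume: in-mask volume above 50% of SUV_peak.
* ``tlg`` — total lesion glycolysis: MTV times the in-mask mean SUV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Radius (mm) of a sphere of volume 1000 mm^3: (4/3) pi r^3 = 1000.
PEAK_SPHERE_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

#: Default volume of interest, mm, per axis.
DEFAULT_VOI_MM = (191.0, 265.0, 173.0)


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: intensities are clipped to center +/- width/2."""

    center: float = 70.0
    width: float = 200.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def low(self) -> float:
        return self.center - self.width / 2.0

    @property
    def high(self) -> float:
        return self.center + self.width / 2.0


@dataclass(frozen=True)
class PetParams:
    suv_peak: float
    suv_mean: float
    suv_max: float
    mtv: float   # cm^3
    tlg: float   # cm^3 * SUV


def window_ct(ct: np.ndarray, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Clip HU values to the window and scale affinely to [0, 1]."""
    ct = np.asarray(ct, dtype=np.float64)
    if not np.all(np.isfinite(ct)):
        raise ValueError("CT volume contains non-finite values")
    return (np.clip(ct, window.low, window.high) - window.low) / window.width


def clip_scale_pet(pet: np.ndarray, cutoff: float = 25.0) -> np.ndarray:
    """Clip SUV at `cutoff` and scale to [0, 1]."""
    if cutoff <= 0:
        raise ValueError("SUV cutoff must be positive")
    pet = np.asarray(pet, dtype=np.float64)
    if np.any(pet < 0):
        raise ValueError("PET volume contains negative SUV")
    return np.minimum(pet, cutoff) / cutoff


def derive_suv_cutoff(suv_max_values, percentile: float = 95.0) -> float:
    """Percentile of per-patient SUV_max over a training cohort.

    Uses numpy's linear-interpolation percentile convention.
    """
    values = np.asarray(list(suv_max_values), dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two patients to derive an SUV cutoff")
    return float(np.percentile(values, percentile))


def crop_voi(volumes: dict[str, np.ndarray], gtvp: np.ndarray,
             gtvn: np.ndarray | None = None,
             voi_mm: tuple[float, float, float] = DEFAULT_VOI_MM,
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
             ) -> dict[str, np.ndarray]:
    """Crop all volumes to a physical VOI centered on the GTV centroid.

    The VOI center is the centroid of GTVp union GTVn, clamped so the VOI
    stays on the grid where possible; axes where the VOI exceeds the grid
    are zero-padded symmetrically (logged).
    """
    gtvp = np.asarray(gtvp)
    shape = gtvp.shape
    target = np.maximum(1, np.round(np.asarray(voi_mm) / np.asarray(spacing))).astype(int)

    union = gtvp.astype(bool)
    if gtvn is not None:
        union = union | np.asarray(gtvn).astype(bool)
    if not union.any():
        raise ValueError("cannot place VOI: GTVp (and GTVn) empty")
    center = np.array(ndimage.center_of_mass(union))

    slices, pads = [], []
    for ax in range(3):
        size, t = shape[ax], target[ax]
        if t >= size:
            lo, hi = 0, size
            before = (t - size) // 2
            pads.append((before, t - size - before))
        else:
            lo = int(round(center[ax] - t / 2.0))
            lo = min(max(lo, 0), size - t)
            hi = lo + t
            pads.append((0, 0))
        slices.append(slice(lo, hi))
    if any(p != (0, 0) for p in pads):
        logger.info("VOI exceeds grid; zero-padding per axis: %s", pads)

    out = {}
    for name, vol in volumes.items():
        cropped = np.asarray(vol)[tuple(slices)]
        if any(p != (0, 0) for p in pads):
            cropped = np.pad(cropped, pads)
        out[name] = cropped
    if "gtvp" in out and not np.asarray(out["gtvp"]).any():
        raise ValueError("GTVp lost entirely by VOI crop")
    return out


def _sphere_kernel(spacing, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> np.ndarray:
    """Binary kernel of voxels whose centers lie within radius_mm."""
    spacing = np.asarray(spacing, dtype=np.float64)
    half = np.floor(radius_mm / spacing).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
                        indexing="ij")
    dist2 = sum(g ** 2 for g in grids)
    return (dist2 <= radius_mm ** 2).astype(np.float64)


def suv_peak(pet: np.ndarray, gtvp: np.ndarray,
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Maximum sphere-mean SUV over candidate centers inside the tumor mask.

    Sphere membership is by voxel-center distance; portions of the sphere
    falling outside the grid are excluded from the mean.
    """
    pet = np.asarray(pet, dtype=np.float64)
    mask = np.asarray(gtvp).astype(bool)
    if not mask.any():
        raise ValueError("GTVp mask is empty")
    kernel = _sphere_kernel(spacing)
    sums = ndimage.convolve(pet, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(pet), kernel, mode="constant", cval=0.0)
    means = sums / counts
    return float(means[mask].max())


def suv_stats(pet: np.ndarray, gtvp: np.ndarray) -> tuple[float, float]:
    """(mean, max) SUV within the tumor mask."""
    mask = np.asarray(gtvp).astype(bool)
    if not mask.any():
        raise ValueError("GTVp mask is empty")
    vals = np.asarray(pet, dtype=np.float64)[mask]
    return float(vals.mean()), float(vals.max())


def mtv(pet: np.ndarray, gtvp: np.ndarray, suv_peak_value: float,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Metabolic tumor volume (cm^3): in-mask voxels at >= 50% of SUV_peak."""
    if suv_peak_value <= 0:
        raise ValueError("SUV_peak must be positive")
    mask = np.asarray(gtvp).astype(bool)
    voxel_mm3 = float(np.prod(spacing))
    n = int(np.count_nonzero(np.asarray(pet)[mask] >= 0.5 * suv_peak_value))
    return n * voxel_mm3 / 1000.0


def tlg(mtv_value: float, suv_mean_gtvp: float) -> float:
    """Total lesion glycolysis: MTV (cm^3) times mean in-mask SUV."""
    if mtv_value < 0 or suv_mean_gtvp < 0:
        raise ValueError("MTV and SUV_mean must be nonnegative")
    return mtv_value * suv_mean_gtvp


def pet_params(pet: np.ndarray, gtvp: np.ndarray,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> PetParams:
    """All standard PET parameters for one patient."""
    peak = suv_peak(pet, gtvp, spacing)
    mean, vmax = suv_stats(pet, gtvp)
    vol = mtv(pet, gtvp, peak, spacing)
    return PetParams(suv_peak=peak, suv_mean=mean, suv_max=vmax,
                     mtv=vol, tlg=tlg(vol, mean))
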