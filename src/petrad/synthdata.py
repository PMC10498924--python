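"""Synthetic PET/CT phantom cohorts.

Generates per-patient PET (SUV), CT (HU), primary-tumor and nodal masks on
a 1 mm isotropic grid, clinical covariates with configurable marginals, and
binary OS/DFS endpoints drawn from a logistic model with planted effects.
Anatomy is deliberately abstract (tumor + nodes on a homogeneous
background): only the statistical contract of the inputs matters to the
downstream pipeline, and every planted parameter is recorded in a
ground-truth table so feature recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

CLINICAL_SITES = ("oral_cavity", "oropharynx", "hypopharynx", "larynx")

#: Default covariate marginals (training-cohort-like values).
DEFAULT_CLINICAL_MARGINALS = {
    "age_mean": 60.2, "age_sd": 7.7,
    "male_fraction": 0.77,
    "smoking_mean": 25.0, "smoking_sd": 22.8,
    "site_probs": (0.079, 0.655, 0.115, 0.151),
    "stage_34_fraction": 0.482,
    "hpv_given_oropharynx": 0.879,  # 80 of 91 oropharyngeal
    "grade_high_fraction": 0.691,
    "charlson_1plus_fraction": 0.381,
}

DEFAULT_EVENT_RATES = {"dfs": 0.49, "os": 0.41}


@dataclass(frozen=True)
class TumorShapeParams:
    """Ranges for tumor geometry; per-patient values are sampled uniformly."""

    semi_axis_range_mm: tuple[float, float] = (8.0, 20.0)
    deform_amplitude_range: tuple[float, float] = (0.0, 0.15)
    deform_scale_mm: float = 6.0


@dataclass(frozen=True)
class SuvParams:
    background: float = 0.5
    tumor_peak_range: tuple[float, float] = (4.0, 18.0)
    node_fraction: float = 0.7          # node SUV relative to tumor SUV
    heterogeneity_amplitude: float = 2.0
    heterogeneity_scale_mm: float = 3.0
    background_noise_sd: float = 0.05


@dataclass(frozen=True)
class CtParams:
    soft_tissue_hu: float = 70.0
    structure_contrast_hu: float = 30.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class PhantomSpec:
    n_patients: int = 25
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    tumor_shape_params: TumorShapeParams = field(default_factory=TumorShapeParams)
    suv_params: SuvParams = field(default_factory=SuvParams)
    ct_params: CtParams = field(default_factory=CtParams)
    n_nodes_range: tuple[int, int] = (0, 2)
    node_radius_range_mm: tuple[float, float] = (3.0, 6.0)
    outcome_coefficients: dict = field(default_factory=dict)  # endpoint -> {name: log-odds}
    event_rate_targets: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_RATES))
    clinical_marginals: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_MARGINALS))
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if any(s <= 0 for s in self.grid_shape) or self.voxel_size <= 0:
            raise ValueError("grid_shape and voxel_size must be positive")
        for rate in self.event_rate_targets.values():
            if not 0.0 < rate < 1.0:
                raise ValueError("event_rate_targets must lie in (0, 1)")


@dataclass
class PatientRecord:
    patient_id: str
    pet: np.ndarray
    ct: np.ndarray
    gtvp_mask: np.ndarray
    gtvn_mask: np.ndarray
    clinical: dict
    os_event: int = 0
    dfs_event: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        shapes = {self.pet.shape, self.ct.shape, self.gtvp_mask.shape, self.gtvn_mask.shape}
        if len(shapes) != 1:
            raise ValueError("pet/ct/masks must share shape")
        if np.any(self.pet < 0):
            raise ValueError("PET must be nonnegative")
        for m in (self.gtvp_mask, self.gtvn_mask):
            if not np.isin(m, (0, 1)).all():
                raise ValueError("masks must be binary")
        if not self.gtvp_mask.any():
            raise ValueError("GTVp mask must be nonempty")


def _smooth_noise(shape, scale_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance smoothed Gaussian field."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(scale_vox, 1e-6))
    sd = noise.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (noise - noise.mean()) / sd


def generate_tumor_mask(semi_axes_mm, grid_shape, seed=None, *,
                        center=None, voxel_size: float = 1.0,
                        deform_amplitude: float = 0.0,
                        deform_scale_mm: float = 6.0):
    """Deformed-ellipsoid binary mask plus its ground-truth descriptors.

    Returns ``(mask, info)`` where ``info`` records the planted semi-axes,
    center and the elongation implied by the two largest semi-axes.
    """
    semi = np.asarray(semi_axes_mm, dtype=np.float64)
    grid_shape = tuple(int(s) for s in grid_shape)
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid_shape)
    center = np.asarray(center, dtype=np.float64)
    semi_vox = semi / voxel_size
    margin = semi_vox * (1.0 + deform_amplitude)
    for ax in range(3):
        if center[ax] - margin[ax] < -0.5 or center[ax] + margin[ax] > grid_shape[ax] - 0.5:
            raise ValueError(
                f"semi-axis {semi[ax]} mm exceeds grid of {grid_shape[ax]} voxels on axis {ax}")

    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in grid_shape], indexing="ij")
    rho = np.sqrt(sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, center, semi_vox)))
    if deform_amplitude > 0:
        rng = np.random.default_rng(seed)
        deform = _smooth_noise(grid_shape, deform_scale_mm / voxel_size, rng)
        mask = rho <= 1.0 + deform_amplitude * deform
    else:
        mask = rho <= 1.0
    labels, n = ndimage.label(mask)
    if n > 1:  # keep the component containing (or nearest) the center
        sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    mask = mask.astype(np.uint8)
    if not mask.any():
        raise ValueError("generated tumor mask is empty")
    srt = np.sort(semi)[::-1]
    info = {
        "semi_axes_mm": tuple(semi),
        "center_vox": tuple(center),
        "elongation_true": float(srt[1] / srt[0]),
        "volume_true_mm3": float(4.0 / 3.0 * np.pi * np.prod(semi)),
    }
    return mask, info


def paint_images(gtvp: np.ndarray, gtvn: np.ndarray, suv_params: SuvParams,
                 ct_params: CtParams, seed=None, *, tumor_suv: float | None = None,
                 heterogeneity: float | None = None, voxel_size: float = 1.0):
    """Render PET and CT volumes for one patient's masks.

    Tumor voxels carry ``tumor_suv`` plus a smoothed zero-mean texture field
    of amplitude ``heterogeneity``; background carries the configured SUV
    with independent noise. CT is soft tissue with added contrast inside
    the structures. Negative SUV after noise is clipped to zero and logged.
    """
    rng = np.random.default_rng(seed)
    shape = gtvp.shape
    if tumor_suv is None:
        tumor_suv = float(np.mean(suv_params.tumor_peak_range))
    if heterogeneity is None:
        heterogeneity = suv_params.heterogeneity_amplitude
    gtvp_b = gtvp.astype(bool)
    gtvn_b = gtvn.astype(bool)
    union = gtvp_b | gtvn_b

    pet = np.full(shape, suv_params.background, dtype=np.float64)
    if suv_params.background_noise_sd > 0:
        pet += rng.normal(0.0, suv_params.background_noise_sd, size=shape)
    pet[gtvp_b] = tumor_suv
    pet[gtvn_b & ~gtvp_b] = suv_params.node_fraction * tumor_suv
    if heterogeneity > 0:
        texture = _smooth_noise(shape, suv_params.heterogeneity_scale_mm / voxel_size, rng)
        pet[union] += heterogeneity * texture[union]
    n_neg = int(np.count_nonzero(pet < 0))
    if n_neg:
        logger.info("clipped %d negative SUV voxels to 0", n_neg)
        np.clip(pet, 0.0, None, out=pet)

    ct = np.full(shape, ct_params.soft_tissue_hu, dtype=np.float64)
    ct[union] += ct_params.structure_contrast_hu
    if ct_params.noise_sd > 0:
        ct += rng.normal(0.0, ct_params.noise_sd, size=shape)
    return pet, ct


def _logistic(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def simulate_outcomes(features: pd.DataFrame, coefficients: dict, seed=None) -> np.ndarray:
    """Bernoulli labels from a logistic model over (standardized) features.

    ``coefficients`` maps feature names to log-odds; the key ``intercept``
    sets the baseline log-odds. Unknown feature names raise with the full
    list of missing names.
    """
    coef = dict(coefficients)
    intercept = float(coef.pop("intercept", 0.0))
    missing = [name for name in coef if name not in features.columns]
    if missing:
        raise KeyError(f"outcome coefficients reference unknown features: {missing}")
    z = np.full(len(features), intercept)
    for name, beta in coef.items():
        if not np.isfinite(beta):
            raise ValueError(f"coefficient for {name!r} is not finite")
        z = z + float(beta) * features[name].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    return (rng.random(len(features)) < _logistic(z)).astype(int)


def _sample_clinical(marg: dict, rng: np.random.Generator) -> dict:
    site = CLINICAL_SITES[rng.choice(4, p=np.asarray(marg["site_probs"]) /
                                     np.sum(marg["site_probs"]))]
    hpv = int(site == "oropharynx" and rng.random() < marg["hpv_given_oropharynx"])
    return {
        "age": float(np.clip(rng.normal(marg["age_mean"], marg["age_sd"]), 18, 95)),
        "gender": int(rng.random() < marg["male_fraction"]),
        "smoking": float(max(0.0, rng.normal(marg["smoking_mean"], marg["smoking_sd"]))),
        "tumor_site": site,
        "stage_group": int(rng.random() < marg["stage_34_fraction"]),
        "hpv_related": hpv,
        "histologic_grade_group": int(rng.random() < marg["grade_high_fraction"]),
        "charlson_group": int(rng.random() < marg["charlson_1plus_fraction"]),
    }


def _place_nodes(spec: PhantomSpec, tumor_center, tumor_semi, rng) -> np.ndarray:
    """Spherical nodal volumes placed around (not inside) the tumor."""
    shape = spec.grid_shape
    gtvn = np.zeros(shape, dtype=np.uint8)
    lo, hi = spec.n_nodes_range
    n_nodes = int(rng.integers(lo, hi + 1))
    coords = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    for _ in range(n_nodes):
        r = rng.uniform(*spec.node_radius_range_mm) / spec.voxel_size
        for _attempt in range(20):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction) + 1e-12
            dist = max(tumor_semi) / spec.voxel_size + r + rng.uniform(2, 10)
            center = np.asarray(tumor_center) + direction * dist
            if np.all(center - r >= 0) and np.all(center + r <= np.asarray(shape) - 1):
                dist2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
                gtvn[dist2 <= r ** 2] = 1
                break
    return gtvn


def generate_cohort(spec: PhantomSpec):
    """Full phantom cohort: ``(records, truth)``.

    ``truth`` holds one row per patient with every planted image parameter
    (semi-axes, elongation, tumor SUV, heterogeneity), mesh-derived shape
    ground truth, the clinical covariates and the simulated endpoints, so
    that downstream feature recovery and selection can be validated.
    """
    from .radiomics.shape import shape_features  # local import; no cycle

    rng = np.random.default_rng(spec.seed)
    shp = spec.tumor_shape_params
    records: list[PatientRecord] = []
    rows: list[dict] = []
    spacing = (spec.voxel_size,) * 3

    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        semi = np.sort(rng.uniform(*shp.semi_axis_range_mm, size=3))[::-1]
        deform = rng.uniform(*shp.deform_amplitude_range)
        max_allowed = (min(spec.grid_shape) * spec.voxel_size / 2.0 - 2.0) / (1.0 + deform)
        semi = np.minimum(semi, max_allowed)
        center = tuple((s - 1) / 2.0 + rng.uniform(-2, 2) for s in spec.grid_shape)
        mask_seed = int(rng.integers(0, 2 ** 31))
        gtvp, info = generate_tumor_mask(
            semi, spec.grid_shape, seed=mask_seed, center=center,
            voxel_size=spec.voxel_size, deform_amplitude=deform,
            deform_scale_mm=shp.deform_scale_mm)
        gtvn = _place_nodes(spec, center, semi, rng)
        gtvn[gtvp.astype(bool)] = 0

        tumor_suv = rng.uniform(*spec.suv_params.tumor_peak_range)
        heterogeneity = rng.uniform(0.0, spec.suv_params.heterogeneity_amplitude)
        paint_seed = int(rng.integers(0, 2 ** 31))
        pet, ct = paint_images(gtvp, gtvn, spec.suv_params, spec.ct_params,
                               seed=paint_seed, tumor_suv=tumor_suv,
                               heterogeneity=heterogeneity, voxel_size=spec.voxel_size)
        clinical = _sample_clinical(spec.clinical_marginals, rng)
        shape_truth = shape_features(gtvp, spacing)
        rec = PatientRecord(pid, pet, ct, gtvp, gtvn, clinical, spacing=spacing)
        rec.validate()
        records.append(rec)
        rows.append({
            "patient_id": pid,
            "semi_a": semi[0], "semi_b": semi[1], "semi_c": semi[2],
            "elongation_true": info["elongation_true"],
            "volume_true_mm3": info["volume_true_mm3"],
            "deform_amplitude": deform,
            "tumor_suv": tumor_suv,
            "heterogeneity": heterogeneity,
            "n_node_voxels": int(gtvn.sum()),
            "sphericity": shape_truth["sphericity"],
            "sphericity_deficit": 1.0 - shape_truth["sphericity"],
            **{k: v for k, v in clinical.items() if k != "tumor_site"},
            "tumor_site": clinical["tumor_site"],
        })

    truth = pd.DataFrame(rows).set_index("patient_id")
    feat = truth.select_dtypes(include=[np.number]).copy()
    sd = feat.std(ddof=0)
    feat = (feat - feat.mean()) / sd.replace(0.0, 1.0)

    for endpoint in ("dfs", "os"):
        coef = dict(spec.outcome_coefficients.get(endpoint, {}))
        if "intercept" not in coef:
            rate = spec.event_rate_targets.get(endpoint, DEFAULT_EVENT_RATES[endpoint])
            coef["intercept"] = float(np.log(rate / (1.0 - rate)))
        label_seed = int(np.random.default_rng(spec.seed + (1 if endpoint == "dfs" else 2))
                         .integers(0, 2 ** 31))
        labels = simulate_outcomes(feat, coef, seed=label_seed)
        truth[f"{endpoint}_event"] = labels
        for rec, lab in zip(records, labels):
            setattr(rec, f"{endpoint}_event", int(lab))
    return records, truth


# -- on-disk format --------------------------------------------------------


def save_cohort(records, truth: pd.DataFrame, out_dir, spec: PhantomSpec | None = None) -> None:
    """Write per-patient NIfTI volumes, the cohort CSV and a spec sidecar."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        pdir = out_dir / rec.patient_id
        pdir.mkdir(exist_ok=True)
        affine = np.diag(list(rec.spacing) + [1.0])
        for name, vol in (("pet", rec.pet), ("ct", rec.ct),
                          ("gtvp", rec.gtvp_mask), ("gtvn", rec.gtvn_mask)):
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                     str(pdir / f"{name}.nii.gz"))
    truth.to_csv(out_dir / "cohort.csv")
    if spec is not None:
        with open(out_dir / "phantom_spec.json", "w") as fh:
            json.dump(dataclasses.asdict(spec), fh, indent=2, default=list)


def load_cohort(in_dir):
    """Read a cohort written by :func:`save_cohort`."""
    import nibabel as nib

    in_dir = Path(in_dir)
    truth = pd.read_csv(in_dir / "cohort.csv", index_col="patient_id")
    records = []
    for pid in truth.index:
        pdir = in_dir / pid
        vols = {}
        for name in ("pet", "ct", "gtvp", "gtvn"):
            img = nib.load(str(pdir / f"{name}.nii.gz"))
            vols[name] = np.asarray(img.dataobj, dtype=np.float64)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        clinical = {k: truth.loc[pid, k] for k in
                    ("age", "gender", "smoking", "tumor_site", "stage_group",
                     "hpv_related", "histologic_grade_group", "charlson_group")}
        rec = PatientRecord(
            pid, vols["pet"], vols["ct"],
            vols["gtvp"].astype(np.uint8), vols["gtvn"].astype(np.uint8),
            clinical, os_event=int(truth.loc[pid, "os_event"]),
            dfs_event=int(truth.loc[pid, "dfs_event"]), spacing=spacing)
        records.append(rec)
    return records, truth
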