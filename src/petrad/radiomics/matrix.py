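"""Cohort-level radiomics feature matrix assembly (the D2 table)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import DiscretizationSpec, discretize
from .firstorder import first_order_features
from .lbp import lbp3d_features
from .shape import shape_features
from .texture import glcm_features, glrlm_features, glszm_features

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """patients x features, with per-column provenance tags."""

    data: pd.DataFrame
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def save(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path)
        with open(path.with_suffix(".provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path, index_col=0)
        prov_path = path.with_suffix(".provenance.json")
        provenance = {}
        if prov_path.exists():
            with open(prov_path) as fh:
                provenance = json.load(fh)
        return cls(data, provenance)


def dedupe_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop columns whose value vectors exactly equal an earlier column.

    Near-duplicates (equal only up to rounding) are kept: the rule is exact
    equality.
    """
    df = matrix.data
    seen: dict[bytes, str] = {}
    keep, dropped = [], []
    for col in df.columns:
        key = np.ascontiguousarray(df[col].to_numpy()).tobytes()
        if key in seen:
            dropped.append(col)
        else:
            seen[key] = col
            keep.append(col)
    if dropped:
        logger.info("dropped %d duplicated feature columns", len(dropped))
    prov = {k: v for k, v in matrix.provenance.items() if k in keep}
    return FeatureMatrix(df[keep].copy(), prov), dropped


def patient_radiomics(pet: np.ndarray, ct: np.ndarray, gtvp: np.ndarray,
                      spacing=(1.0, 1.0, 1.0),
                      discretizations: tuple[DiscretizationSpec, ...] = (
                          DiscretizationSpec(bins=32),),
                      lbp_points: int = 8, lbp_radius: float = 1.0,
                      ) -> tuple[dict[str, float], dict[str, dict]]:
    """All configured radiomics features for one patient, within GTVp.

    Texture and histogram-dependent first-order features are computed per
    modality and per discretization setting; shape once from the mask; LBP
    per modality from raw intensities.
    """
    feats: dict[str, float] = {}
    prov: dict[str, dict] = {}

    for name, value in shape_features(gtvp, spacing).items():
        col = f"shape_{name}"
        feats[col] = value
        prov[col] = {"modality": "mask", "family": "shape", "discretization": None}

    for modality, vol in (("pet", pet), ("ct", ct)):
        for spec in discretizations:
            tag = spec.tag
            fo = first_order_features(vol, gtvp, spec)
            for name, value in fo.items():
                col = f"{modality}_{tag}_firstorder_{name}"
                feats[col] = value
                prov[col] = {"modality": modality, "family": "firstorder",
                             "discretization": tag}
            levels = discretize(vol, gtvp, spec)
            for family, fam_feats in (
                    ("glcm", glcm_features(levels)),
                    ("glszm", glszm_features(levels)),
                    ("glrlm", glrlm_features(levels))):
                for name, value in fam_feats.items():
                    col = f"{modality}_{tag}_{family}_{name}"
                    feats[col] = value
                    prov[col] = {"modality": modality, "family": family,
                                 "discretization": tag}
        for name, value in lbp3d_features(vol, gtvp, n_points=lbp_points,
                                          radius=lbp_radius).items():
            col = f"{modality}_{name}"
            feats[col] = value
            prov[col] = {"modality": modality, "family": "lbp", "discretization": None}
    return feats, prov


def extract_radiomics(records, discretizations=(DiscretizationSpec(bins=32),),
                      lbp_points: int = 8, lbp_radius: float = 1.0,
                      deduplicate: bool = True) -> FeatureMatrix:
    """The D2 feature matrix for a cohort of patient records."""
    rows, prov = {}, {}
    for rec in records:
        feats, p = patient_radiomics(rec.pet, rec.ct, rec.gtvp_mask, rec.spacing,
                                     discretizations=discretizations,
                                     lbp_points=lbp_points, lbp_radius=lbp_radius)
        rows[rec.patient_id] = feats
        prov = p
    matrix = FeatureMatrix(pd.DataFrame.from_dict(rows, orient="index"), prov)
    if deduplicate:
        matrix, _ = dedupe_features(matrix)
    return matrix
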