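"""Clinical/PET table encoding (D1) and design-matrix assembly.

D1 is exactly 14 columns: age, gender, smoking pack-years, a 4-column
tumor-site one-hot, TNM8 stage group (I-II vs III-IV), HPV relation,
histologic grade group (low/moderate vs high), Charlson group (0 vs 1-6),
and the three standard PET parameters. Missing values reject the row --
no imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .radiomics.matrix import FeatureMatrix

logger = logging.getLogger(__name__)

SITES = ("oral_cavity", "oropharynx", "hypopharynx", "larynx")

D1_COLUMNS = (
    "age", "gender", "smoking",
    "site_oral_cavity", "site_oropharynx", "site_hypopharynx", "site_larynx",
    "stage_group", "hpv_related", "histologic_grade_group", "charlson_group",
    "suv_peak", "mtv", "tlg",
)

D1_CONTINUOUS = ("age", "smoking", "suv_peak", "mtv", "tlg")

_REQUIRED = ("age", "gender", "smoking", "tumor_site", "stage_group",
             "hpv_related", "histologic_grade_group", "charlson_group",
             "suv_peak", "mtv", "tlg")


def _coerce_binary(value, column: str) -> int:
    """Accept 0/1, booleans, or the raw categorical levels."""
    mapping = {
        "gender": {"female": 0, "male": 1},
        "stage_group": {"i-ii": 0, "iii-iv": 1},
        "histologic_grade_group": {"low": 0, "moderate": 0, "low/moderate": 0, "high": 1},
    }
    if isinstance(value, str):
        lowered = value.strip().lower()
        table = mapping.get(column, {})
        if lowered in table:
            return table[lowered]
        raise ValueError(f"cannot interpret {value!r} for column {column!r}")
    if column == "charlson_group" and not np.isnan(value):
        # raw Charlson index 0-6 dichotomizes as 0 vs 1-6
        return int(float(value) > 0)
    iv = int(value)
    if iv not in (0, 1) and column != "charlson_group":
        raise ValueError(f"binary column {column!r} got {value!r}")
    return iv


def encode_d1(clinical: pd.DataFrame) -> tuple[FeatureMatrix, list[str]]:
    """Encode the clinical + PET-parameter table into the 14-column D1.

    Rows with any missing required value are rejected (returned in the
    second element) rather than imputed.
    """
    missing_cols = [c for c in _REQUIRED if c not in clinical.columns]
    if missing_cols:
        raise KeyError(f"clinical table is missing columns: {missing_cols}")

    rows, rejected = {}, []
    for pid, row in clinical.iterrows():
        if row[list(_REQUIRED)].isna().any():
            rejected.append(str(pid))
            continue
        site = str(row["tumor_site"]).strip().lower().replace(" ", "_")
        if site not in SITES:
            raise ValueError(f"unknown tumor site {row['tumor_site']!r} for {pid}")
        encoded = {
            "age": float(row["age"]),
            "gender": _coerce_binary(row["gender"], "gender"),
            "smoking": float(row["smoking"]),
            **{f"site_{s}": int(s == site) for s in SITES},
            "stage_group": _coerce_binary(row["stage_group"], "stage_group"),
            "hpv_related": int(row["hpv_related"]),
            "histologic_grade_group": _coerce_binary(
                row["histologic_grade_group"], "histologic_grade_group"),
            "charlson_group": _coerce_binary(row["charlson_group"], "charlson_group"),
            "suv_peak": float(row["suv_peak"]),
            "mtv": float(row["mtv"]),
            "tlg": float(row["tlg"]),
        }
        rows[pid] = encoded
    if rejected:
        logger.warning("rejected %d rows with missing values: %s", len(rejected), rejected)
    df = pd.DataFrame.from_dict(rows, orient="index")[list(D1_COLUMNS)]
    prov = {c: {"modality": "clinical", "family": "d1", "discretization": None}
            for c in df.columns}
    return FeatureMatrix(df, prov), rejected


def standardize_continuous(df: pd.DataFrame, train_ids,
                           continuous: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score continuous columns using statistics from training rows only.

    Uses the sample standard deviation (ddof=1). Binary columns (at most
    two distinct training values) are left untouched, as are zero-spread
    columns (flagged in the log). Returns the scaled frame and the scaler
    parameters so the same transform can be re-applied.
    """
    train_ids = list(train_ids)
    if not train_ids:
        raise ValueError("train subset is empty")
    train = df.loc[train_ids]
    if continuous is None:
        continuous = [c for c in df.columns
                      if df[c].dtype.kind in "fi" and train[c].nunique() > 2]
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for col in continuous:
        mean = float(train[col].mean())
        sd = float(train[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            logger.warning("column %r has zero spread on the training rows; left unscaled", col)
            continue
        out[col] = (df[col] - mean) / sd
        params[col] = (mean, sd)
    return out, params


def apply_scaler(df: pd.DataFrame, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    out = df.copy()
    for col, (mean, sd) in params.items():
        out[col] = (df[col] - mean) / sd
    return out


def assemble_inputs(d1: FeatureMatrix | None, d2: FeatureMatrix | None,
                    selection: list[str] | None = None) -> FeatureMatrix:
    """Column-concatenate D1/D2 and optionally restrict to a selection.

    An explicitly empty selection is an error (a model cannot be trained on
    zero features); unknown selection names are listed in the error.
    """
    parts = [m for m in (d1, d2) if m is not None]
    if not parts:
        raise ValueError("at least one of D1/D2 must be provided")
    index = parts[0].data.index
    for m in parts[1:]:
        if not m.data.index.equals(index):
            raise ValueError("patient ids of D1 and D2 are not aligned")
    data = pd.concat([m.data for m in parts], axis=1)
    prov = {}
    for m in parts:
        prov.update(m.provenance)
    if data.columns.duplicated().any():
        raise ValueError("overlapping column names between D1 and D2")
    if selection is not None:
        if len(selection) == 0:
            raise ValueError("empty feature selection")
        unknown = [s for s in selection if s not in data.columns]
        if unknown:
            raise KeyError(f"selected features not present: {unknown}")
        data = data[list(selection)]
        prov = {k: v for k, v in prov.items() if k in data.columns}
    return FeatureMatrix(data, prov)
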