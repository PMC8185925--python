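"""Covariate encodings shared by all scans.

Coding conventions (kept fixed so coefficients are comparable across
runs): sex female=0 / male=1; smoking ever=1 / never=0; age in years,
untransformed; treatment flags 0/1; disease-activity group lower=0 /
higher=1 (boundary DAS28-CRP = 3.2 belongs to lower); CRP group low=0 /
high=1 (boundary 3.0 mg/L belongs to low).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAS28_BOUNDARY = 3.2
CRP_BOUNDARY = 3.0

SEX_LEVELS = {"female": 0, "male": 1, "f": 0, "m": 1}
SMOKING_LEVELS = {"never": 0, "ever": 1, "former": 1, "current": 1}


def encode_sex(values: pd.Series) -> pd.Series:
    enc = values.astype(str).str.lower().map(SEX_LEVELS)
    if enc.isna().any():
        bad = sorted(values[enc.isna()].astype(str).unique())
        raise ValueError(f"unknown sex levels: {bad}")
    return enc.astype(float)


def encode_smoking(values: pd.Series) -> pd.Series:
    enc = values.astype(str).str.lower().map(SMOKING_LEVELS)
    if enc.isna().any():
        bad = sorted(values[enc.isna()].astype(str).unique())
        raise ValueError(f"unknown smoking levels: {bad}")
    return enc.astype(float)


def assign_activity_group(das28_crp) -> np.ndarray | str:
    """'lower' when DAS28-CRP <= 3.2, 'higher' above; vectorized.

    Raises on missing or non-finite scores.
    """
    arr = np.asarray(das28_crp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("DAS28-CRP contains missing or non-finite values")
    if (arr < 0).any():
        raise ValueError("DAS28-CRP must be nonnegative")
    out = np.where(arr <= DAS28_BOUNDARY, "lower", "higher")
    return out.item() if np.isscalar(das28_crp) or arr.ndim == 0 else out


def assign_crp_group(crp) -> np.ndarray | str:
    """'low' when CRP <= 3.0 mg/L, 'high' above."""
    arr = np.asarray(crp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("CRP contains missing or non-finite values")
    out = np.where(arr <= CRP_BOUNDARY, "low", "high")
    return out.item() if np.isscalar(crp) or arr.ndim == 0 else out


def model_frame(meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate frame aligned to the metadata rows."""
    out = pd.DataFrame(index=meta.index)
    out["age"] = meta["age"].astype(float)
    out["sex"] = encode_sex(meta["sex"])
    if "smoking" in meta:
        out["smoking"] = encode_smoking(meta["smoking"])
    if "das28_crp" in meta:
        out["activity"] = (meta["das28_crp"].astype(float)
                           > DAS28_BOUNDARY).astype(float)
    if "crp" in meta:
        out["crp_group"] = (meta["crp"].astype(float)
                            > CRP_BOUNDARY).astype(float)
    for col in ("bmi", "duration_years", "visit", "das28_crp"):
        if col in meta:
            out[col] = meta[col].astype(float)
    from rametab.simulate import TREATMENTS
    for t in TREATMENTS:
        if t in meta:
            out[t] = meta[t].astype(float)
    return out
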