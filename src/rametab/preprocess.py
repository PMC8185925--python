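"""Metabolon-style "scaled imputed" preparation of an abundance matrix.

Three steps, applied in this order:

1. ``median_scale`` — divide each metabolite by the median of its
   observed values so every metabolite's median equals 1.
2. ``filter_by_missingness`` — drop metabolites missing in more than a
   fraction (default 20%) of samples (strictly greater than).
3. ``impute_minimum`` — fill remaining missing cells with the
   metabolite's minimum observed value, the convention for values below
   the detection limit.

The abundance matrix is a pandas DataFrame with sample IDs as the index
and metabolite IDs as columns; missing cells are NaN.  Medians are
computed over observed values only, before imputation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "median_scale",
    "filter_by_missingness",
    "impute_minimum",
    "preprocess",
]


def _validate(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate sample IDs in abundance matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate metabolite IDs in abundance matrix")
    if (matrix < 0).any().any():
        bad = matrix.columns[(matrix < 0).any()].tolist()
        raise ValueError(f"negative abundances in metabolites: {bad[:5]}")


def median_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each metabolite so the median of observed values is 1.

    Missing cells are preserved; within-metabolite ratios are unchanged.
    Raises if any metabolite is all-missing or has a non-positive median.
    """
    _validate(matrix)
    medians = matrix.median(axis=0, skipna=True)
    bad = medians.index[~(medians > 0)].tolist()
    if bad:
        raise ValueError(
            f"metabolites with all-missing values or non-positive median: {bad[:10]}")
    return matrix / medians


def filter_by_missingness(matrix: pd.DataFrame, threshold: float = 0.20
                          ) -> tuple[pd.DataFrame, list]:
    """Remove metabolites missing in more than `threshold` of samples.

    The inequality is strict: a metabolite missing in exactly 20% of
    samples survives a 0.20 threshold.  Column order of survivors is
    preserved.  Returns (filtered matrix, removed metabolite IDs).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    frac = matrix.isna().mean(axis=0)
    removed = frac.index[frac > threshold].tolist()
    for m in removed:
        logger.info("removing metabolite %s: missing fraction %.3f > %.2f",
                    m, frac[m], threshold)
    return matrix.drop(columns=removed), removed


def impute_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Fill missing cells with the metabolite's minimum observed value."""
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing metabolites cannot be imputed: {bad[:10]}")
    return matrix.fillna(matrix.min(axis=0, skipna=True))


def preprocess(matrix: pd.DataFrame, threshold: float = 0.20
               ) -> tuple[pd.DataFrame, list]:
    """Full pipeline: median-scale, missingness-filter, minimum-impute.

    Medians are computed before imputation, so every metabolite of the
    result has median 1 with respect to its originally observed cells.
    Returns (processed matrix, removed metabolite IDs).
    """
    scaled = median_scale(matrix)
    kept, removed = filter_by_missingness(scaled, threshold)
    return impute_minimum(kept), removed
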