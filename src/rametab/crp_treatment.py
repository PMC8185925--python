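"""Treatment-association scans and the two-stage CRP-group analysis.

Both analyses model metabolite abundance as the response of a marginal
random-intercept linear model.  The treatment scan relates each
candidate metabolite to each of the five treatment-use flags
(methotrexate, prednisone, non-methotrexate csDMARDs, TNFi-bDMARDs,
non-TNFi-bDMARDs) one at a time.  The CRP analysis is two-stage: every
candidate covariate is first screened marginally against the
metabolite's abundance; the covariates found significant then enter an
adjusted model together with the CRP group (high > 3.0 mg/L vs low),
and the metabolite is called differentially abundant when the CRP-group
coefficient stays significant in that adjusted model.  The CRP group
always enters stage 2, whether or not its own screen was significant —
otherwise the final test would be undefined.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from rametab.covariates import model_frame
from rametab.mixedlm import lmm_scan
from rametab.simulate import TREATMENTS

logger = logging.getLogger(__name__)

__all__ = ["treatment_association_scan", "crp_adjusted_scan",
           "CRP_COVARIATES"]

# candidate covariates of the CRP stage-1 screen (BMI and disease
# duration deliberately absent); smoking is coded ever/never
CRP_COVARIATES = ("crp_group", "sex", "age", "smoking", "methotrexate",
                  "prednisone", "csdmard", "tnfi_bdmard", "non_tnfi_bdmard")


def treatment_association_scan(abundance: pd.DataFrame, meta: pd.DataFrame,
                               candidates=None, alpha: float = 0.05
                               ) -> tuple[pd.DataFrame, list[str]]:
    """Marginal mixed scan of abundance on each treatment flag.

    Fits ``abundance ~ treatment + (1|patient)`` per metabolite and
    treatment.  Returns the long-format scan table (one row per
    metabolite x treatment) and the list of candidates with no
    significant association with any treatment.  Treatments with a
    single observed level are skipped with a warning.
    """
    ids = list(abundance.columns if candidates is None else candidates)
    missing = [m for m in ids if m not in abundance.columns]
    if missing:
        raise KeyError(f"candidate metabolites absent: {missing}")
    mf = model_frame(meta)
    groups = meta["patient_id"].to_numpy()
    Y = abundance[ids].to_numpy(dtype=float).T  # (M, n)
    rows = []
    for t in TREATMENTS:
        if t not in mf.columns:
            continue
        flag = mf[t].to_numpy()
        if len(np.unique(flag)) < 2:
            logger.warning("treatment %s has a single level; skipped", t)
            continue
        X = np.column_stack([np.ones(len(flag)), flag])
        res = lmm_scan(Y, X, groups)
        for i, m in enumerate(ids):
            rows.append({"metabolite_id": m, "treatment": t,
                         "coefficient": float(res.beta[i, 1]),
                         "se": float(res.se[i, 1]),
                         "statistic": float(res.tstat[i, 1]),
                         "df": float(res.df[i, 1]),
                         "p_value": float(res.p_value[i, 1]),
                         "significant": bool(res.p_value[i, 1] < alpha)})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no testable treatment flags in metadata")
    associated = set(table.loc[table["significant"], "metabolite_id"])
    unassociated = [m for m in ids if m not in associated]
    table = table.sort_values(["treatment", "p_value", "metabolite_id"]
                              ).reset_index(drop=True)
    return table, unassociated


def crp_adjusted_scan(abundance: pd.DataFrame, meta: pd.DataFrame,
                      candidates=None, alpha: float = 0.05) -> pd.DataFrame:
    """Two-stage covariate-screened CRP-group differential abundance.

    Stage 1 screens each covariate in ``CRP_COVARIATES`` marginally
    (``abundance ~ covariate + (1|patient)``); stage 2 refits abundance
    on CRP group plus all stage-1-significant covariates with the
    patient random intercept.  One row per metabolite with the screened
    covariates, the stage-2 CRP coefficient and p-value, a direction
    label, and the ``significant`` flag.
    """
    ids = list(abundance.columns if candidates is None else candidates)
    if not ids:
        raise ValueError("candidate set is empty")
    missing = [m for m in ids if m not in abundance.columns]
    if missing:
        raise KeyError(f"candidate metabolites absent: {missing}")
    mf = model_frame(meta)
    if "crp_group" not in mf.columns:
        raise ValueError("CRP missing from metadata")
    groups = meta["patient_id"].to_numpy()
    Y = abundance[ids].to_numpy(dtype=float).T
    n = Y.shape[1]

    stage1_sig = {}
    for cov in CRP_COVARIATES:
        if cov not in mf.columns:
            continue
        x = mf[cov].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            continue
        X = np.column_stack([np.ones(n), x])
        res = lmm_scan(Y, X, groups)
        stage1_sig[cov] = res.p_value[:, 1] < alpha

    rows = []
    for i, m in enumerate(ids):
        screened = [c for c, sig in stage1_sig.items() if sig[i]]
        terms = ["crp_group"] + [c for c in screened if c != "crp_group"]
        X = np.column_stack([np.ones(n)]
                            + [mf[c].to_numpy(dtype=float) for c in terms])
        res = lmm_scan(Y[i], X, groups)
        coef = float(res.beta[0, 1])
        p = float(res.p_value[0, 1])
        rows.append({"metabolite_id": m,
                     "screened_covariates": ",".join(screened),
                     "crp_coefficient": coef,
                     "crp_p": p,
                     "direction": ("higher_in_high_crp" if coef >= 0
                                   else "higher_in_low_crp"),
                     "significant": bool(p < alpha)})
    return (pd.DataFrame(rows)
            .sort_values(["crp_p", "metabolite_id"])
            .reset_index(drop=True))
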