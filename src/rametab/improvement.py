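"""EULAR treatment-response classification and visit-change scans.

A patient improves by delta = DAS28-CRP(visit 1) - DAS28-CRP(visit 2)
(positive = improvement) and attains the visit-2 score.  The
conventional EULAR grid grades the response:

* good      — delta > 1.2 and attained <= 3.2
* moderate  — delta > 1.2 with attained > 3.2, or
              0.6 < delta <= 1.2 with attained <= 5.1
* none      — otherwise

"Improved" means good or moderate.  Within each patient subset
(improved / non-improved), the visit-change scan fits, per metabolite,
``abundance ~ visit + age + sex + (1|patient)`` and reports metabolites
whose visit coefficient is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rametab.covariates import model_frame
from rametab.mixedlm import lmm_scan

logger = logging.getLogger(__name__)

__all__ = ["EularResponse", "eular_response", "classify_patients",
           "visit_change_scan"]

# conventional cut-points: improvement thresholds 1.2 / 0.6, attained
# thresholds 3.2 / 5.1 (config-exposed because DAS28-CRP-specific
# adaptations of the grid differ)
DELTA_GOOD = 1.2
DELTA_MODERATE = 0.6
ATTAINED_LOW = 3.2
ATTAINED_HIGH = 5.1


@dataclass
class EularResponse:
    patient_id: str | None
    delta: float
    attained: float
    category: str               # good | moderate | none

    @property
    def improved(self) -> bool:
        return self.category in ("good", "moderate")


def eular_response(das28_v1: float, das28_v2: float,
                   patient_id: str | None = None,
                   thresholds: tuple[float, float, float, float] = (
                       DELTA_GOOD, DELTA_MODERATE, ATTAINED_LOW,
                       ATTAINED_HIGH)) -> EularResponse:
    """Grade one patient's visit-1 to visit-2 response on the EULAR grid."""
    if not (np.isfinite(das28_v1) and np.isfinite(das28_v2)):
        raise ValueError("both DAS28-CRP scores must be finite")
    d_good, d_mod, a_low, a_high = thresholds
    delta = das28_v1 - das28_v2
    attained = das28_v2
    if delta > d_good and attained <= a_low:
        cat = "good"
    elif (delta > d_good and attained > a_low) or \
            (d_mod < delta <= d_good and attained <= a_high):
        cat = "moderate"
    else:
        cat = "none"
    return EularResponse(patient_id, float(delta), float(attained), cat)


def classify_patients(meta: pd.DataFrame) -> pd.DataFrame:
    """EULAR response per discovery patient with both visits.

    Returns one row per patient: delta, attained, category, improved.
    """
    disc = meta[meta.get("cohort", "discovery") == "discovery"]
    v1 = disc[disc["visit"] == 1].set_index("patient_id")["das28_crp"]
    v2 = disc[disc["visit"] == 2].set_index("patient_id")["das28_crp"]
    common = v1.index.intersection(v2.index)
    rows = []
    for p in common:
        r = eular_response(float(v1[p]), float(v2[p]), patient_id=p)
        rows.append({"patient_id": p, "delta": r.delta,
                     "attained": r.attained, "category": r.category,
                     "improved": r.improved})
    return pd.DataFrame(rows).set_index("patient_id")


def visit_change_scan(abundance: pd.DataFrame, meta: pd.DataFrame,
                      patient_subset, alpha: float = 0.05,
                      adjust: tuple[str, ...] = ("age", "sex")
                      ) -> pd.DataFrame:
    """Per-metabolite visit-1 to visit-2 abundance change within a subset.

    Requires every subset patient to have both visits and at least 3
    patients.  Metabolites constant within the subset are excluded with
    a logged reason.
    """
    subset = list(patient_subset)
    if len(subset) < 3:
        raise ValueError("need at least 3 patients for the visit-change scan")
    mask = meta["patient_id"].isin(subset).to_numpy()
    sub_meta = meta.loc[mask]
    counts = sub_meta.groupby("patient_id")["visit"].nunique()
    incomplete = counts.index[counts < 2].tolist()
    missing = [p for p in subset if p not in counts.index]
    if incomplete or missing:
        raise ValueError(
            f"patients without both visits: {incomplete + missing}")
    sub_ab = abundance.loc[mask]
    mf = model_frame(sub_meta)
    adjust = tuple(c for c in adjust if mf[c].nunique() > 1)
    keep = [m for m in sub_ab.columns
            if np.ptp(sub_ab[m].to_numpy()) > 0]
    for m in sub_ab.columns.difference(keep):
        logger.info("excluding constant metabolite %s from visit scan", m)
    Y = sub_ab[keep].to_numpy(dtype=float).T
    visit2 = (sub_meta["visit"].to_numpy() == 2).astype(float)
    X = np.column_stack([np.ones(len(visit2)), visit2]
                        + [mf[c].to_numpy(dtype=float) for c in adjust])
    res = lmm_scan(Y, X, sub_meta["patient_id"].to_numpy())
    out = pd.DataFrame({
        "metabolite_id": keep,
        "coefficient": res.beta[:, 1],
        "se": res.se[:, 1],
        "statistic": res.tstat[:, 1],
        "df": res.df[:, 1],
        "p_value": res.p_value[:, 1],
    })
    out["significant"] = out["p_value"] < alpha
    return out.sort_values(["p_value", "metabolite_id"]).reset_index(drop=True)
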