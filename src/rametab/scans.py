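"""Disease-activity group analyses: per-metabolite differential-abundance
scan with confounder control, fold changes, pathway enrichment, and the
cohort-level confounder screens.

Samples are split into "lower" (DAS28-CRP <= 3.2) and "higher" activity
groups.  The differential-abundance scan fits, per metabolite, a
random-intercept logistic regression of the activity group on metabolite
abundance adjusted for the screened confounders (age and sex by
default), with patient ID as the random effect.  Raw per-coefficient
p-values at alpha = 0.05 define the hit set — no multiplicity
correction, mirroring the criterion the analysis is built around; a
Benjamini-Hochberg column can be requested separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.stats.multitest import multipletests

from rametab.covariates import (assign_activity_group, model_frame)
from rametab.mixedlm import MixedModelSpec, fit_logistic_mm

logger = logging.getLogger(__name__)

__all__ = [
    "assign_activity_group",
    "differential_abundance_scan",
    "log2_fold_change",
    "hypergeometric_enrichment",
    "confounder_screen",
    "EnrichmentResult",
    "ConfounderScreenReport",
]


def differential_abundance_scan(abundance: pd.DataFrame, meta: pd.DataFrame,
                                alpha: float = 0.05,
                                adjust: tuple[str, ...] = ("age", "sex"),
                                add_fdr: bool = False) -> pd.DataFrame:
    """Per-metabolite logistic mixed scan of activity group on abundance.

    Returns one row per metabolite with the metabolite coefficient, Wald
    z statistic and p-value, the log2 fold change (higher vs lower
    group), a ``significant`` flag at `alpha`, and a ``fallback_used``
    flag for non-converged (e.g. separated) fits.  Constant metabolites
    are excluded with a logged reason.
    """
    groups = assign_activity_group(meta["das28_crp"])
    if len(np.unique(groups)) < 2:
        raise ValueError("both activity groups must be present")
    mf = model_frame(meta)
    adjust = tuple(c for c in adjust if mf[c].nunique() > 1)
    base = pd.DataFrame({
        "activity": mf["activity"],
        "patient": meta["patient_id"],
        **{c: mf[c] for c in adjust},
    }, index=meta.index)
    labels = pd.Series(groups, index=meta.index)

    rows = []
    for m in abundance.columns:
        x = abundance[m]
        if np.ptp(x.to_numpy()) == 0:
            logger.info("excluding constant metabolite %s from scan", m)
            continue
        data = base.assign(abundance=x)
        spec = MixedModelSpec("activity", ["abundance", *adjust], "patient",
                              family="binomial")
        fit = fit_logistic_mm(data, spec)
        rows.append({
            "metabolite_id": m,
            "coefficient": fit.coefficients["abundance"],
            "se": fit.standard_errors["abundance"],
            "statistic": fit.statistics["abundance"],
            "p_value": fit.p_values["abundance"],
            "log2_fold_change": log2_fold_change(abundance, labels, m),
            "fallback_used": not fit.converged,
        })
    res = pd.DataFrame(rows)
    res["significant"] = (res["p_value"] < alpha) & ~res["fallback_used"]
    if add_fdr:
        res["fdr_bh"] = multipletests(res["p_value"], method="fdr_bh")[1]
    return res.sort_values(["p_value", "metabolite_id"]).reset_index(drop=True)


def log2_fold_change(abundance: pd.DataFrame, labels: pd.Series,
                     metabolite_id: str) -> float:
    """log2 of (mean abundance in higher group / mean in lower group).

    Group means are taken over the scaled-imputed values.
    """
    values = abundance[metabolite_id]
    hi = values[np.asarray(labels) == "higher"]
    lo = values[np.asarray(labels) == "lower"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both groups must be non-empty")
    denom = lo.mean()
    if denom == 0:
        raise ValueError(f"zero mean in lower group for {metabolite_id}")
    return float(np.log2(hi.mean() / denom))


@dataclass
class EnrichmentResult:
    pathway: str
    universe_size: int
    pathway_size: int
    hits_drawn: int
    hits_in_pathway: int
    fold_enrichment: float
    p_value: float


def hypergeometric_enrichment(hits, pathway: str, annotation: pd.DataFrame,
                              universe=None) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of `hits` in a sub-pathway.

    P(X >= k) for k pathway members among n hits drawn from a universe
    of N metabolites containing K pathway members; fold enrichment is
    (k/n) / (K/N).
    """
    if universe is None:
        universe = set(annotation.index)
    universe = set(universe)
    if not universe:
        raise ValueError("empty metabolite universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    members = set(annotation.index[annotation["sub_pathway"] == pathway])
    if not members:
        raise ValueError(f"pathway {pathway!r} not present in annotation")
    N = len(universe)
    K = len(members & universe)
    n = len(hits)
    k = len(hits & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if n > 0 else float("nan")
    return EnrichmentResult(pathway, N, K, n, k, float(fold), p)


@dataclass
class ConfounderScreenReport:
    """Cohort-level screens used to fix the scan adjustment set."""

    fisher: pd.DataFrame          # per dichotomized covariate vs activity
    mcnemar: pd.DataFrame         # per treatment, visit 1 vs visit 2 use
    wilcoxon_das28_p: float       # paired DAS28-CRP across visits
    adjustment_set: list[str]     # covariates with Fisher p < alpha


def _dichotomies(meta: pd.DataFrame) -> dict[str, np.ndarray]:
    mf = model_frame(meta)
    out = {
        "age_gt_60": (mf["age"] > 60).to_numpy(),
        "sex_male": (mf["sex"] == 1).to_numpy(),
    }
    if "bmi" in mf:
        out["bmi_gt_30"] = (mf["bmi"] > 30).to_numpy()
    if "duration_years" in mf:
        out["duration_gt_9y"] = (mf["duration_years"] > 9).to_numpy()
    if "smoking" in mf:
        out["smoking_ever"] = (mf["smoking"] == 1).to_numpy()
    from rametab.simulate import TREATMENTS
    for t in TREATMENTS:
        if t in mf:
            out[t] = (mf[t] == 1).to_numpy()
    return out


# screened dichotomy -> covariate entering the scans' fixed effects
_ADJUSTMENT_NAME = {"age_gt_60": "age", "sex_male": "sex",
                    "bmi_gt_30": "bmi", "duration_gt_9y": "duration_years",
                    "smoking_ever": "smoking"}


def confounder_screen(meta: pd.DataFrame, alpha: float = 0.05
                      ) -> ConfounderScreenReport:
    """Fisher/McNemar/Wilcoxon screens for the discovery cohort.

    (a) Fisher's exact test of each dichotomized covariate against the
    activity group, with the sample odds ratio and the exact conditional
    95% CI; (b) exact McNemar test per treatment for paired visit-1 vs
    visit-2 use; (c) Wilcoxon signed-rank of paired DAS28-CRP across
    visits.  Covariates with Fisher p < alpha form the adjustment set
    handed to the scans.
    """
    higher = np.asarray(assign_activity_group(meta["das28_crp"])) == "higher"
    rows = []
    for name, flag in _dichotomies(meta).items():
        a = int(np.sum(flag & higher))
        b = int(np.sum(flag & ~higher))
        c = int(np.sum(~flag & higher))
        d = int(np.sum(~flag & ~higher))
        if flag.all() or (~flag).all():
            rows.append({"covariate": name, "odds_ratio": np.nan,
                         "p_value": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "testable": False})
            continue
        table = np.array([[a, b], [c, d]])
        p = stats.fisher_exact(table)[1]
        sample_or = (a * d) / (b * c) if b * c > 0 else np.inf
        res = stats.contingency.odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(0.95)
        rows.append({"covariate": name, "odds_ratio": sample_or,
                     "p_value": float(p), "ci_low": float(ci.low),
                     "ci_high": float(ci.high), "testable": True})
    fisher = pd.DataFrame(rows)

    # paired visit-1 vs visit-2 treatment use per patient
    from rametab.simulate import TREATMENTS
    disc = meta[meta.get("cohort", "discovery") == "discovery"]
    v1 = disc[disc["visit"] == 1].set_index("patient_id")
    v2 = disc[disc["visit"] == 2].set_index("patient_id")
    common = v1.index.intersection(v2.index)
    mrows = []
    for t in TREATMENTS:
        if t not in disc.columns:
            continue
        x1 = v1.loc[common, t].astype(int)
        x2 = v2.loc[common, t].astype(int)
        tab = np.array([[int(((x1 == 1) & (x2 == 1)).sum()),
                         int(((x1 == 1) & (x2 == 0)).sum())],
                        [int(((x1 == 0) & (x2 == 1)).sum()),
                         int(((x1 == 0) & (x2 == 0)).sum())]])
        res = mcnemar(tab, exact=True)
        mrows.append({"treatment": t, "discordant_10": int(tab[0, 1]),
                      "discordant_01": int(tab[1, 0]),
                      "p_value": float(res.pvalue)})
    mcnemar_df = pd.DataFrame(mrows)

    d1 = v1.loc[common, "das28_crp"].to_numpy(dtype=float)
    d2 = v2.loc[common, "das28_crp"].to_numpy(dtype=float)
    if np.allclose(d1, d2):
        wil_p = 1.0
    else:
        wil_p = float(stats.wilcoxon(d1, d2).pvalue)

    adjust = [_ADJUSTMENT_NAME.get(r["covariate"], r["covariate"])
              for _, r in fisher.iterrows()
              if r["testable"] and r["p_value"] < alpha]
    return ConfounderScreenReport(fisher, mcnemar_df, wil_p, adjust)
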