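"""Quantitative disease-activity prediction from plasma metabolomes.

Per-metabolite linear mixed scans select features associated with
DAS28-CRP; a Gaussian identity-link GLM built on the selected metabolite
abundances predicts DAS28-CRP; performance is estimated with a
leakage-safe, patient-grouped leave-one-out cross-validation in which
feature selection is re-run inside every fold on the training patients
only.

The two building blocks are scikit-learn estimators and compose with
sklearn pipelines and model selection:

* :class:`MixedLMSelector` — feature selection by per-metabolite
  random-intercept LMM p-value (Satterthwaite) at a chosen alpha;
* :class:`MinimumNormRegression` — least squares via the pseudoinverse,
  returning the minimum-norm solution when predictors outnumber samples
  (the deterministic, hyperparameter-free "no selection" baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from rametab.covariates import model_frame
from rametab.mixedlm import lmm_scan

__all__ = [
    "MixedLMSelector",
    "MinimumNormRegression",
    "FeatureSet",
    "PredictionReport",
    "das28_association_scan",
    "build_glm",
    "grouped_loocv",
    "evaluate_validation",
    "spearman_ci",
]


class MixedLMSelector(SelectorMixin, BaseEstimator):
    """Select features whose LMM coefficient on y is significant.

    For each feature x_j a linear mixed model
    ``y ~ 1 + x_j + covariates + (1 | groups)`` is fit by REML; the
    feature is retained when the Satterthwaite t p-value of its
    coefficient is below ``alpha``.  Without ``groups`` every sample is
    its own group and the fit reduces to OLS with n - p df.

    Parameters
    ----------
    alpha : float
        Per-feature selection level (default 0.05).

    Attributes
    ----------
    support_ : bool array (n_features,)
    pvalues_, coefficients_, dfs_ : float arrays (n_features,)
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, groups=None, covariates=None):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        X = validate_data(self, X, ensure_min_features=1)
        y = np.asarray(y, dtype=float)
        n, M = X.shape
        if groups is None:
            groups = np.arange(n)
        cov = (np.empty((n, 0)) if covariates is None
               else np.asarray(covariates, dtype=float))
        p = 2 + cov.shape[1]
        Xb = np.empty((M, n, p))
        Xb[:, :, 0] = 1.0
        Xb[:, :, 1] = X.T
        Xb[:, :, 2:] = cov[None, :, :]
        variable = np.ptp(X, axis=0) > 0
        res = lmm_scan(y, Xb[variable], groups)
        pvals = np.full(M, np.nan)
        coefs = np.full(M, np.nan)
        ses = np.full(M, np.nan)
        dfs = np.full(M, np.nan)
        pvals[variable] = res.p_value[:, 1]
        coefs[variable] = res.beta[:, 1]
        ses[variable] = res.se[:, 1]
        dfs[variable] = res.df[:, 1]
        self.pvalues_ = pvals
        self.coefficients_ = coefs
        self.standard_errors_ = ses
        self.dfs_ = dfs
        self.support_ = variable & (pvals < self.alpha)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class MinimumNormRegression(RegressorMixin, BaseEstimator):
    """Least-squares linear model solved by pseudoinverse.

    With fewer samples than predictors the fit is the minimum-norm
    least-squares solution — it interpolates the training data, which is
    exactly the overfitting behaviour the no-selection baseline exposes.
    An intercept column is always included (and is not penalized or
    treated specially beyond being part of the minimum-norm system).
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=2,
                          ensure_min_features=0)
        y = np.asarray(y, dtype=float)
        A = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        w, *_ = np.linalg.lstsq(A, y, rcond=None)
        if self.fit_intercept:
            self.intercept_ = float(w[0])
            self.coef_ = w[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = w
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, ensure_min_features=0)
        return self.intercept_ + X @ self.coef_


@dataclass
class FeatureSet:
    """Metabolites passing a selection rule, with provenance."""

    metabolite_ids: list[str]
    alpha: float
    source: str                 # "full_discovery" or "cv_fold"
    fold_id: str | None = None


@dataclass
class PredictionReport:
    """Held-out predictions of DAS28-CRP with error and rank summaries.

    Predictions are deliberately not clipped to the DAS28-CRP range;
    negative predictions are reported as such.
    """

    per_sample: pd.DataFrame    # sample_id, observed, predicted, abs_error
    mae: float
    sd_abs_error: float
    spearman_rho: float | None = None
    rho_ci95: tuple[float, float] | None = None
    rho_p: float | None = None


def das28_association_scan(abundance: pd.DataFrame, meta: pd.DataFrame,
                           alpha: float = 0.05,
                           adjust: tuple[str, ...] = ("age", "sex"),
                           ) -> tuple[pd.DataFrame, FeatureSet]:
    """Metabolome-wide linear mixed scan for DAS28-CRP association.

    Per metabolite: ``das28_crp ~ metabolite + age + sex + (1|patient)``
    fit by REML, with the Satterthwaite p-value for the metabolite
    coefficient.  Returns the full scan table (sorted by p) and the
    FeatureSet of metabolites with p < alpha, ordered by ascending p.
    """
    if meta["das28_crp"].isna().any():
        raise ValueError("DAS28-CRP missing for some samples")
    mf = model_frame(meta)
    # covariates constant in this subset are inestimable and dropped
    adjust = tuple(c for c in adjust if mf[c].nunique() > 1)
    sel = MixedLMSelector(alpha=alpha)
    sel.fit(abundance.to_numpy(dtype=float), mf["das28_crp"].to_numpy(),
            groups=meta["patient_id"].to_numpy(),
            covariates=mf[list(adjust)].to_numpy())
    res = pd.DataFrame({
        "metabolite_id": abundance.columns,
        "coefficient": sel.coefficients_,
        "se": sel.standard_errors_,
        "p_value": sel.pvalues_,
        "df": sel.dfs_,
        "significant": sel.support_,
    })
    res["direction"] = np.where(res["coefficient"] >= 0, "positive",
                                "negative")
    res = res.sort_values(["p_value", "metabolite_id"]).reset_index(drop=True)
    ids = res.loc[res["significant"], "metabolite_id"].tolist()
    return res, FeatureSet(ids, alpha, "full_discovery")


@dataclass
class Das28Predictor:
    """A fitted GLM over a fixed metabolite feature list."""

    model: MinimumNormRegression
    features: list[str]

    def predict(self, abundance: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in abundance.columns]
        if missing:
            raise KeyError(f"features absent from abundance matrix: {missing}")
        if self.features:
            return self.model.predict(
                abundance[self.features].to_numpy(dtype=float))
        return np.full(len(abundance), self.model.intercept_)


def build_glm(abundance: pd.DataFrame, meta: pd.DataFrame,
              features=None) -> Das28Predictor:
    """Fit the Gaussian identity-link GLM of DAS28-CRP on metabolites.

    ``features`` is a FeatureSet, a list of metabolite IDs, or None for
    all metabolites (minimum-norm least squares when p >= n).  An empty
    feature list yields the intercept-only model (training mean).
    """
    if isinstance(features, FeatureSet):
        features = features.metabolite_ids
    if features is None:
        features = list(abundance.columns)
    features = list(features)
    missing = [f for f in features if f not in abundance.columns]
    if missing:
        raise KeyError(f"features absent from abundance matrix: {missing}")
    y = meta["das28_crp"].to_numpy(dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 training samples")
    model = MinimumNormRegression()
    if features:
        model.fit(abundance[features].to_numpy(dtype=float), y)
    else:
        model.fit(np.empty((len(y), 0)), y)
    return Das28Predictor(model, features)


def grouped_loocv(abundance: pd.DataFrame, meta: pd.DataFrame,
                  alpha: float = 0.05, with_selection: bool = True,
                  adjust: tuple[str, ...] = ("age", "sex"),
                  ) -> tuple[PredictionReport, list[FeatureSet]]:
    """Patient-grouped leave-one-out CV with nested feature selection.

    One fold per patient: all of that patient's samples are held out;
    when ``with_selection`` the DAS28-CRP association scan runs on the
    remaining patients only (never seeing the held-out samples), and the
    fold's GLM uses the features it selects.  Folds follow patient ID
    sort order, so the report is bit-reproducible.
    """
    patients = np.asarray(meta["patient_id"])
    unique_patients = sorted(pd.unique(patients))
    if len(unique_patients) < 3:
        raise ValueError("grouped LOOCV needs at least 3 patients")
    rows = []
    feature_sets: list[FeatureSet] = []
    for pat in unique_patients:
        held = patients == pat
        if not held.any():
            raise ValueError(f"patient {pat} has no samples")
        tr_ab, tr_meta = abundance.loc[~held], meta.loc[~held]
        if with_selection:
            _, fs = das28_association_scan(tr_ab, tr_meta, alpha=alpha,
                                           adjust=adjust)
            fold_features = fs.metabolite_ids
        else:
            fold_features = None
        feature_sets.append(FeatureSet(
            fold_features if fold_features is not None
            else list(abundance.columns),
            alpha, "cv_fold", fold_id=str(pat)))
        predictor = build_glm(tr_ab, tr_meta, fold_features)
        pred = predictor.predict(abundance.loc[held])
        obs = meta.loc[held, "das28_crp"].to_numpy(dtype=float)
        for sid, o, p in zip(abundance.index[held], obs, pred):
            rows.append({"sample_id": sid, "observed": float(o),
                         "predicted": float(p),
                         "abs_error": float(abs(o - p))})
    per_sample = pd.DataFrame(rows)
    return _summarize(per_sample), feature_sets


def spearman_ci(rho: float, n: int, level: float = 0.95
                ) -> tuple[float, float]:
    """Fisher z-transform CI for a rank correlation, SE = 1/sqrt(n-3)."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = np.arctanh(rho)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def _summarize(per_sample: pd.DataFrame, with_rho: bool = True
               ) -> PredictionReport:
    err = per_sample["abs_error"].to_numpy()
    mae = float(err.mean())
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    rho = ci = rho_p = None
    n = len(per_sample)
    if with_rho and n >= 3:
        obs = per_sample["observed"]
        pred = per_sample["predicted"]
        if obs.nunique() > 1 and pred.nunique() > 1:
            r = stats.spearmanr(obs, pred)
            rho, rho_p = float(r.statistic), float(r.pvalue)
            if n >= 4 and abs(rho) < 1.0:
                ci = spearman_ci(rho, n)
    return PredictionReport(per_sample, mae, sd, rho, ci, rho_p)


def evaluate_validation(predictor: Das28Predictor,
                        abundance: pd.DataFrame,
                        meta: pd.DataFrame) -> PredictionReport:
    """Apply a fitted GLM to a validation cohort and summarize errors.

    Reports per-sample predictions, MAE with the SD of absolute errors,
    and Spearman's rho with a two-sided t-approximation p-value and a
    Fisher-z 95% CI (omitted with a warning below 4 samples).
    """
    pred = predictor.predict(abundance)
    obs = meta["das28_crp"].to_numpy(dtype=float)
    per_sample = pd.DataFrame({
        "sample_id": abundance.index,
        "observed": obs,
        "predicted": pred,
        "abs_error": np.abs(obs - pred),
    })
    report = _summarize(per_sample)
    if len(per_sample) < 4 and report.spearman_rho is not None:
        import warnings
        warnings.warn("fewer than 4 validation samples; rho CI omitted")
        report.rho_ci95 = None
    return report
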