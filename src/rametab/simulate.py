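"""Synthetic longitudinal RA metabolomics cohorts with known ground truth.

The generator emulates the design of a two-visit discovery cohort plus a
single-visit validation cohort: per-metabolite log-normal abundances, a
sparse set of metabolites with true linear effects on DAS28-CRP, a
per-patient random intercept, CRP as a noisy monotone (exp-linear)
transform of DAS28-CRP, demographic and treatment covariates with
realistic frequencies, and left-censored (detection-limit) missingness.

Defaults mirror the emulated study: 64 patients x 2 visits (128
discovery samples), 12 single-visit validation patients, 686 metabolites
median-scaled to 1, DAS28-CRP clipped to [1.2, 7.0], ~69% female, and
treatment-use frequencies of roughly 75/45/31/36/9 percent for
methotrexate, prednisone, non-methotrexate csDMARDs, TNFi-bDMARDs and
non-TNFi-bDMARDs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_cohort",
           "inject_missingness", "TREATMENTS"]

TREATMENTS = ("methotrexate", "prednisone", "csdmard", "tnfi_bdmard",
              "non_tnfi_bdmard")

_SUBPATHWAYS = [
    ("Acylcarnitine", "Lipid"),
    ("Lysophospholipid", "Lipid"),
    ("Secondary bile acid metabolism", "Lipid"),
    ("Fatty acid, dicarboxylate", "Lipid"),
    ("Tyrosine metabolism", "Amino acid"),
    ("Tryptophan metabolism", "Amino acid"),
    ("Leucine, isoleucine and valine metabolism", "Amino acid"),
    ("Urea cycle; arginine and proline metabolism", "Amino acid"),
    ("Glutathione metabolism", "Amino acid"),
    ("Aminosugar metabolism", "Carbohydrate"),
    ("Glycolysis and gluconeogenesis", "Carbohydrate"),
    ("Purine metabolism", "Nucleotide"),
    ("Hemoglobin and porphyrin metabolism", "Cofactors and vitamins"),
    ("Nicotinate and nicotinamide metabolism", "Cofactors and vitamins"),
    ("Food component/plant", "Xenobiotics"),
    ("Benzoate metabolism", "Xenobiotics"),
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are on the DAS28-CRP scale per unit of median-scaled
    abundance; abundance_log_sd is the SD of log-abundance; CRP is in
    mg/L.
    """

    n_patients: int = 64
    n_visits: int = 2
    n_validation_patients: int = 12
    n_metabolites: int = 686
    n_causal: int = 5
    effect_size_sd: float = 0.8
    patient_intercept_sd: float = 0.8
    residual_sd: float = 0.5
    abundance_log_sd: float = 0.8
    missing_rate_target: float = 0.10
    das28_range: tuple[float, float] = (1.2, 7.0)
    crp_noise_sd: float = 0.8
    seed: int = 0
    # mean structure
    das28_mean: float = 3.0
    age_effect: float = 0.01          # DAS28 units per year above the mean age
    sex_effect: float = -0.2          # DAS28 shift for male (female = 0)
    # CRP coupling: log CRP = crp_intercept + crp_slope * DAS28 + noise
    crp_intercept: float = -0.8
    crp_slope: float = 0.55
    crp_floor: float = 0.1
    # missingness structure
    missing_metabolite_fraction: float = 0.25
    high_missing_fraction: float = 0.03
    high_missing_rate: float = 0.30
    # covariate frequencies
    female_fraction: float = 0.69
    age_mean: float = 63.0
    age_sd: float = 10.5
    bmi_mean: float = 30.8
    bmi_sd: float = 5.5
    smoking_ever_fraction: float = 0.60
    duration_range: tuple[float, float] = (0.5, 25.0)
    treatment_fractions: dict = field(default_factory=lambda: {
        "methotrexate": 0.75, "prednisone": 0.45, "csdmard": 0.31,
        "tnfi_bdmard": 0.36, "non_tnfi_bdmard": 0.09})
    treatment_switch_prob: float = 0.03
    # secondary true effects on abundance (log-scale shifts, in units of
    # abundance_log_sd)
    n_visit_shift: int = 5
    visit_shift_size: float = 1.0
    n_treatment_effect: int = 2
    treatment_effect_size: float = 1.0
    # annotation
    acylcarnitine_size: int = 40

    def __post_init__(self):
        if self.n_causal > self.n_metabolites:
            raise ValueError("n_causal cannot exceed n_metabolites")
        for name in ("effect_size_sd", "patient_intercept_sd", "residual_sd",
                     "abundance_log_sd", "crp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate_target < 1.0:
            raise ValueError("missing_rate_target must be in [0, 1)")
        if not self.das28_range[0] < self.das28_range[1]:
            raise ValueError("das28_range must satisfy min < max")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    causal_ids: list[str]
    causal_betas: dict[str, float]
    intercept: float
    patient_intercepts: dict[str, float]
    visit_shift_ids: list[str]
    treatment_effect_ids: dict[str, list[str]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def inject_missingness(matrix: pd.DataFrame, rate: float, seed: int = 0,
                       column_fraction: float = 1.0) -> pd.DataFrame:
    """Left-censor each affected metabolite at its `rate` quantile.

    Values strictly below the per-metabolite quantile become missing;
    observed values are unchanged.  With ``column_fraction < 1`` a seeded
    random subset of metabolites is censored.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = matrix.copy()
    cols = np.asarray(matrix.columns)
    if column_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = int(round(column_fraction * len(cols)))
        cols = rng.choice(cols, size=k, replace=False)
    if rate == 0.0 or len(cols) == 0:
        return out
    cut = out[cols].quantile(rate, axis=0)
    censored = out[cols].lt(cut, axis=1)
    out[cols] = out[cols].mask(censored)
    return out


def _annotation(config: SimulationConfig, metab_ids: list[str],
                rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_metabolites
    sub = np.empty(n, dtype=object)
    k_acyl = min(config.acylcarnitine_size, n)
    acyl_idx = rng.choice(n, size=k_acyl, replace=False)
    other = [s for s, _ in _SUBPATHWAYS[1:]]
    sub[:] = rng.choice(other, size=n)
    sub[acyl_idx] = "Acylcarnitine"
    super_map = dict(_SUBPATHWAYS)
    hmdb = [f"HMDB{7000000 + i:07d}" if rng.random() < 0.7 else None
            for i in range(n)]
    return pd.DataFrame({
        "metabolite_id": metab_ids,
        "super_pathway": [super_map[s] for s in sub],
        "sub_pathway": sub,
        "hmdb_id": hmdb,
    }).set_index("metabolite_id")


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               SimulationTruth]:
    """Generate one discovery + validation cohort bundle.

    Returns (abundance, metadata, annotation, truth).  The abundance
    matrix holds raw (unscaled) intensities with left-censored missing
    cells, discovery and validation samples stacked; metadata carries a
    ``cohort`` column distinguishing them.  DAS28-CRP is

        das28 = b0 + sum_c beta_c * m_c + age/sex terms + u_patient + eps

    with m_c the metabolite's abundance divided by its discovery-cohort
    median (the same scale the preprocessing pipeline reproduces), then
    clipped to ``das28_range``.
    """
    rng = np.random.default_rng(config.seed)
    nm = config.n_metabolites
    n_disc = config.n_patients * config.n_visits
    n_val = config.n_validation_patients
    n_all = n_disc + n_val

    metab_ids = [f"M{i + 1:04d}" for i in range(nm)]
    disc_patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    val_patients = [f"V{i + 1:03d}" for i in range(n_val)]

    # raw abundances: per-metabolite log-normal with arbitrary location
    log_loc = rng.normal(np.log(100.0), 1.0, size=nm)
    z = rng.normal(0.0, 1.0, size=(n_all, nm))
    log_raw = log_loc[None, :] + config.abundance_log_sd * z

    # row bookkeeping: discovery rows first (patient-major, visit-minor)
    patient = np.array(
        [p for p in disc_patients for _ in range(config.n_visits)]
        + val_patients)
    visit = np.array(
        [v + 1 for _ in disc_patients for v in range(config.n_visits)]
        + [1] * n_val)
    sample_ids = [f"{p}_V{v}" for p, v in zip(patient, visit)]
    cohort = np.array(["discovery"] * n_disc + ["validation"] * n_val)

    # secondary structure on abundance (log scale), disjoint metabolite sets
    pool = rng.permutation(nm)
    causal_idx = pool[:config.n_causal]
    pos = config.n_causal
    shift_idx = pool[pos:pos + config.n_visit_shift]
    pos += config.n_visit_shift
    treatment_idx: dict[str, np.ndarray] = {}
    for t in TREATMENTS:
        treatment_idx[t] = pool[pos:pos + config.n_treatment_effect]
        pos += config.n_treatment_effect

    # covariates (patient level)
    all_patients = disc_patients + val_patients
    n_pat = len(all_patients)
    sex_pat = np.where(rng.random(n_pat) < config.female_fraction,
                       "female", "male")
    age_pat = np.clip(rng.normal(config.age_mean, config.age_sd, n_pat), 25, 90)
    bmi_pat = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n_pat), 16, 55)
    smoking_pat = np.where(rng.random(n_pat) < config.smoking_ever_fraction,
                           "ever", "never")
    duration_pat = rng.uniform(*config.duration_range, n_pat)
    pat_index = {p: i for i, p in enumerate(all_patients)}
    row_pat = np.array([pat_index[p] for p in patient])

    treat_flags = {}
    for t in TREATMENTS:
        base = (rng.random(n_pat) < config.treatment_fractions[t])
        flags = base[row_pat].astype(int)
        # rare visit-2 switches keep paired (McNemar) screens exercisable
        switch = (visit == 2) & (rng.random(n_all) < config.treatment_switch_prob)
        flags = np.where(switch, 1 - flags, flags)
        treat_flags[t] = flags
        for j in treatment_idx[t]:
            log_raw[:, j] += (config.treatment_effect_size
                              * config.abundance_log_sd * flags)

    for j in shift_idx:
        log_raw[:, j] += (config.visit_shift_size * config.abundance_log_sd
                          * (visit == 2) * (cohort == "discovery"))

    raw = np.exp(log_raw)

    # median-scaled (by discovery medians) abundances drive DAS28-CRP
    disc_median = np.median(raw[:n_disc], axis=0)
    scaled = raw / disc_median[None, :]

    # fixed-magnitude, random-sign effects: every causal metabolite carries
    # a detectable signal and the coefficient SD equals effect_size_sd
    betas = config.effect_size_sd * rng.choice([-1.0, 1.0],
                                               size=config.n_causal)
    u_pat = rng.normal(0.0, config.patient_intercept_sd, size=n_pat)
    eps = rng.normal(0.0, config.residual_sd, size=n_all)
    causal_part = scaled[:, causal_idx] @ betas if config.n_causal else 0.0
    mean_causal = (scaled[:n_disc, causal_idx].mean(axis=0) @ betas
                   if config.n_causal else 0.0)
    b0 = config.das28_mean - mean_causal
    das28 = (b0 + causal_part
             + config.age_effect * (age_pat[row_pat] - config.age_mean)
             + config.sex_effect * (sex_pat[row_pat] == "male")
             + u_pat[row_pat] + eps)
    das28 = np.clip(das28, *config.das28_range)

    log_crp = (config.crp_intercept + config.crp_slope * das28
               + rng.normal(0.0, config.crp_noise_sd, n_all))
    crp = np.maximum(config.crp_floor, np.exp(log_crp))

    abundance = pd.DataFrame(raw, index=pd.Index(sample_ids, name="sample_id"),
                             columns=metab_ids)

    # left-censored missingness on a seeded subset of metabolites
    if config.missing_rate_target > 0 and config.missing_metabolite_fraction > 0:
        n_miss = int(round(config.missing_metabolite_fraction * nm))
        miss_cols = rng.choice(metab_ids, size=n_miss, replace=False)
        part = inject_missingness(abundance[list(miss_cols)],
                                  config.missing_rate_target)
        abundance[list(miss_cols)] = part
    if config.high_missing_fraction > 0:
        n_high = int(round(config.high_missing_fraction * nm))
        rest = [m for m in metab_ids]
        high_cols = rng.choice(rest, size=n_high, replace=False)
        part = inject_missingness(abundance[list(high_cols)],
                                  config.high_missing_rate)
        abundance[list(high_cols)] = part

    metadata = pd.DataFrame({
        "patient_id": patient,
        "cohort": cohort,
        "visit": visit,
        "das28_crp": das28,
        "crp": crp,
        "age": age_pat[row_pat],
        "sex": sex_pat[row_pat],
        "bmi": bmi_pat[row_pat],
        "smoking": smoking_pat[row_pat],
        "duration_years": duration_pat[row_pat],
        **{t: treat_flags[t] for t in TREATMENTS},
    }, index=pd.Index(sample_ids, name="sample_id"))

    annotation = _annotation(config, metab_ids, rng)

    truth = SimulationTruth(
        causal_ids=[metab_ids[i] for i in causal_idx],
        causal_betas={metab_ids[i]: float(b)
                      for i, b in zip(causal_idx, betas)},
        intercept=float(b0),
        patient_intercepts={p: float(u_pat[pat_index[p]])
                            for p in all_patients},
        visit_shift_ids=[metab_ids[i] for i in shift_idx],
        treatment_effect_ids={t: [metab_ids[i] for i in idx]
                              for t, idx in treatment_idx.items()},
        seed=config.seed,
    )
    return abundance, metadata, annotation, truth
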