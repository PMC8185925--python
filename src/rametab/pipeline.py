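"""End-to-end orchestration of the discovery pipeline.

``run_pipeline`` executes, in order: simulate (optional) -> preprocess
-> confounder screen -> activity-group differential-abundance scan with
pathway enrichment -> DAS28-CRP association scan -> grouped
leave-one-out CV (with and without nested feature selection) ->
validation-cohort prediction -> treatment scan -> CRP-group adjusted
scan -> EULAR improvement scans.  Every stage writes a TSV/JSON under
the output directory and the run ends with a manifest (config hash,
seed, per-stage row counts, file checksums) that is byte-identical
across reruns with the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from rametab import __version__
from rametab.covariates import assign_activity_group
from rametab.crp_treatment import crp_adjusted_scan, treatment_association_scan
from rametab.improvement import classify_patients, visit_change_scan
from rametab.io import read_tables, write_tables
from rametab.predict import (build_glm, das28_association_scan,
                             evaluate_validation, grouped_loocv)
from rametab.preprocess import preprocess
from rametab.scans import (confounder_screen, differential_abundance_scan,
                           hypergeometric_enrichment)
from rametab.simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    output_dir: str = "rametab_out"
    alpha: float = 0.05
    missingness_threshold: float = 0.20
    with_fdr_column: bool = False
    enrichment_pathway: str = "Acylcarnitine"
    seed: int = 0
    # either a simulation block ...
    simulation: dict | None = None
    # ... or paths to the three input tables
    abundance_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.missingness_threshold < 1:
            raise ValueError("missingness_threshold must be in [0, 1)")
        has_paths = all(p is not None for p in (
            self.abundance_path, self.metadata_path, self.annotation_path))
        if self.simulation is None and not has_paths:
            raise ValueError("provide either a simulation block or all "
                             "three input table paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g",
                 index=index)


_REQUIRED_META = ("patient_id", "visit", "das28_crp", "crp", "age", "sex")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, rows: int, *paths: Path) -> None:
        stages.append({"stage": name, "rows": int(rows),
                       "outputs": {p.name: _sha256(p) for p in sorted(paths)}})

    # -- inputs -----------------------------------------------------------
    if config.simulation is not None:
        sim_cfg = SimulationConfig(**{"seed": config.seed,
                                      **config.simulation})
        abundance, meta, annotation, truth = simulate_cohort(sim_cfg)
        paths = write_tables(outdir, abundance, meta, annotation)
        truth_path = outdir / "truth.json"
        truth.to_json(truth_path)
        record("simulate", len(abundance), *paths.values(), truth_path)
    else:
        abundance, meta, annotation = read_tables(
            config.abundance_path, config.metadata_path,
            config.annotation_path)

    missing_cols = [c for c in _REQUIRED_META if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing required columns: {missing_cols}")

    # -- preprocess (scale -> filter -> impute) over all samples ----------
    processed, removed = preprocess(abundance,
                                    threshold=config.missingness_threshold)
    proc_path = outdir / "scaled_imputed.tsv"
    _write_tsv(processed, proc_path, index=True)
    removed_path = outdir / "removed_metabolites.json"
    removed_path.write_text(json.dumps(sorted(removed), indent=1))
    record("preprocess", len(processed.columns), proc_path, removed_path)

    disc = meta["cohort"] == "discovery" if "cohort" in meta else \
        pd.Series(True, index=meta.index)
    d_ab, d_meta = processed.loc[disc], meta.loc[disc]
    v_ab, v_meta = processed.loc[~disc], meta.loc[~disc]

    # -- confounder screens -> adjustment set ------------------------------
    screen = confounder_screen(d_meta, alpha=config.alpha)
    fisher_path = outdir / "confounder_fisher.tsv"
    _write_tsv(screen.fisher, fisher_path)
    mcnemar_path = outdir / "confounder_mcnemar.tsv"
    _write_tsv(screen.mcnemar, mcnemar_path)
    screen_json = outdir / "confounder_summary.json"
    screen_json.write_text(json.dumps({
        "wilcoxon_das28_p": screen.wilcoxon_das28_p,
        "adjustment_set": screen.adjustment_set}, indent=1, sort_keys=True))
    record("confounder-screen", len(screen.fisher), fisher_path,
           mcnemar_path, screen_json)
    adjust = tuple(c for c in screen.adjustment_set
                   if c in ("age", "sex", "smoking", "bmi", "duration_years"))

    # -- activity-group scan + enrichment ---------------------------------
    da = differential_abundance_scan(d_ab, d_meta, alpha=config.alpha,
                                     adjust=adjust,
                                     add_fdr=config.with_fdr_column)
    da_path = outdir / "differential_abundance.tsv"
    da_out = da.merge(annotation, left_on="metabolite_id", right_index=True,
                      how="left")
    _write_tsv(da_out, da_path)
    hits = da.loc[da["significant"], "metabolite_id"].tolist()
    try:
        enr = hypergeometric_enrichment(hits, config.enrichment_pathway,
                                        annotation,
                                        universe=processed.columns)
        enr_frame = pd.DataFrame([dataclasses.asdict(enr)])
    except ValueError:
        enr_frame = pd.DataFrame()
    enr_path = outdir / "enrichment.tsv"
    _write_tsv(enr_frame, enr_path)
    record("scan-groups", len(da), da_path, enr_path)

    # -- DAS28-CRP association scan ---------------------------------------
    scan, features = das28_association_scan(d_ab, d_meta,
                                            alpha=config.alpha,
                                            adjust=adjust)
    scan_path = outdir / "das28_association.tsv"
    _write_tsv(scan.merge(annotation, left_on="metabolite_id",
                          right_index=True, how="left"), scan_path)
    record("scan-das28", len(scan), scan_path)

    # -- grouped LOOCV with and without selection -------------------------
    cv_summary = {}
    for label, with_sel in (("with_selection", True),
                            ("without_selection", False)):
        report, folds = grouped_loocv(d_ab, d_meta, alpha=config.alpha,
                                      with_selection=with_sel, adjust=adjust)
        pred_path = outdir / f"cv_predictions_{label}.tsv"
        _write_tsv(report.per_sample, pred_path)
        folds_path = outdir / f"cv_features_{label}.json"
        folds_path.write_text(json.dumps(
            {f.fold_id: f.metabolite_ids for f in folds},
            indent=1, sort_keys=True))
        cv_summary[label] = {"mae": report.mae,
                             "sd_abs_error": report.sd_abs_error,
                             "spearman_rho": report.spearman_rho}
        record(f"predict-cv-{label}", len(report.per_sample), pred_path,
               folds_path)
    cv_json = outdir / "cv_summary.json"
    cv_json.write_text(json.dumps(cv_summary, indent=1, sort_keys=True))

    # -- validation-cohort prediction -------------------------------------
    val_summary = {}
    if len(v_ab):
        for label, feats in (("with_selection", features),
                             ("without_selection", None)):
            predictor = build_glm(d_ab, d_meta, feats)
            report = evaluate_validation(predictor, v_ab, v_meta)
            vp = outdir / f"validation_predictions_{label}.tsv"
            _write_tsv(report.per_sample, vp)
            val_summary[label] = {
                "mae": report.mae, "sd_abs_error": report.sd_abs_error,
                "spearman_rho": report.spearman_rho,
                "rho_ci95": report.rho_ci95, "rho_p": report.rho_p}
            record(f"predict-validation-{label}", len(report.per_sample), vp)
    val_json = outdir / "validation_summary.json"
    val_json.write_text(json.dumps(val_summary, indent=1, sort_keys=True))

    # -- treatment / CRP-group scans over the union of hits ---------------
    union = sorted(set(hits) | set(features.metabolite_ids))
    if union:
        treat, unassociated = treatment_association_scan(
            d_ab, d_meta, candidates=union, alpha=config.alpha)
        tr_path = outdir / "treatment_association.tsv"
        _write_tsv(treat, tr_path)
        un_path = outdir / "treatment_unassociated.json"
        un_path.write_text(json.dumps(unassociated, indent=1))
        record("scan-treatment", len(treat), tr_path, un_path)

        crp = crp_adjusted_scan(d_ab, d_meta, candidates=union,
                                alpha=config.alpha)
        crp_path = outdir / "crp_adjusted.tsv"
        _write_tsv(crp, crp_path)
        record("scan-crp", len(crp), crp_path)

    # -- EULAR improvement scans ------------------------------------------
    responses = classify_patients(d_meta)
    resp_path = outdir / "eular_response.tsv"
    _write_tsv(responses, resp_path, index=True)
    outputs = [resp_path]
    n_rows = len(responses)
    for label, improved in (("improved", True), ("non_improved", False)):
        pats = responses.index[responses["improved"] == improved].tolist()
        path = outdir / f"visit_change_{label}.tsv"
        if len(pats) >= 3:
            vc = visit_change_scan(d_ab, d_meta, pats, alpha=config.alpha,
                                   adjust=adjust)
            _write_tsv(vc, path)
        else:
            _write_tsv(pd.DataFrame(), path)
        outputs.append(path)
    record("scan-improvement", n_rows, *outputs)

    # -- manifest ----------------------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "n_samples": int(len(processed)),
        "n_metabolites": int(len(processed.columns)),
        "activity_group_counts": pd.Series(
            assign_activity_group(d_meta["das28_crp"])
        ).value_counts().to_dict(),
        "stages": stages,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
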