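"""Pipeline orchestration: the three models run independently on one design.

A validated configuration drives simulate/load -> encode -> Model 1
(time-dependent competing-risk fit with separation handling and optional
AIC-guided selection) -> Model 2 (MSM with stabilized IPTW) -> Model 3
(Boruta), and renders HR tables plus selection, weight, and decision
reports.  A stage failure is recorded in the report and later independent
stages still run.  All artifacts embed a fingerprint (SHA-256 of the
resolved configuration) and identical config + seed gives identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import boruta as boruta_mod
from . import msm as msm_mod
from . import selection as selection_mod
from . import simulate as simulate_mod
from .exposure import (DEFAULT_CATALOGUE, InvalidArgumentError,
                       build_interval_scheme, encode_exposures,
                       read_exposure_records)
from .survival import (FitResult, compute_vif, covariate_model_matrix,
                       expand_counting_process, fit_td_hazard, read_covariates,
                       read_outcomes)

logger = logging.getLogger(__name__)

_CONFIG_SCHEMA = {
    "preset": (str, type(None)),
    "n_patients": (int, type(None)),
    "exposures_csv": (str, type(None)),
    "covariates_csv": (str, type(None)),
    "outcomes_csv": (str, type(None)),
    "window_start": int, "window_end": int, "n_intervals": int,
    "horizon": int,
    "catalogue": (list, tuple),
    "endpoint": str,
    "coding": str, "ties": str,
    "select": bool,
    "restrict_terms": (list, type(None)),
    "msm_truncate_percentiles": (list, type(None)),
    "boruta_iterations": int,
    "boruta_trees": int,
    "seed": int,
    "out_dir": (str, type(None)),
}


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-loadable)."""

    preset: str | None = "null"
    n_patients: int | None = None
    exposures_csv: str | None = None
    covariates_csv: str | None = None
    outcomes_csv: str | None = None
    window_start: int = -7
    window_end: int = 30
    n_intervals: int = 5
    horizon: int = 180
    catalogue: tuple = DEFAULT_CATALOGUE
    endpoint: str = "grade2_4"
    coding: str = "persistent"
    ties: str = "efron"
    select: bool = True
    restrict_terms: list | None = None
    msm_truncate_percentiles: list | None = None
    boruta_iterations: int = 100
    boruta_trees: int = 500
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        problems = []
        for name, typ in _CONFIG_SCHEMA.items():
            if not isinstance(getattr(self, name), typ):
                problems.append(f"{name} has invalid type")
        files = (self.exposures_csv, self.covariates_csv, self.outcomes_csv)
        if self.preset is None and any(f is None for f in files):
            problems.append("either a preset or all three input CSVs required")
        if problems:
            raise InvalidArgumentError("invalid config: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def resolved(self) -> dict:
        """Analysis-relevant configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d["catalogue"] = list(self.catalogue)
        d.pop("out_dir", None)
        return d

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()


def render_hr_table(fit: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """One row per term: HR, 95% CI, p, significance flag (warning banner if
    the fit did not converge)."""
    tab = pd.DataFrame({
        "term": fit.terms,
        "hr": fit.hazard_ratios,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "p": fit.p_values,
    })
    tab["significant"] = tab["p"] < alpha
    tab.attrs["warning"] = (None if fit.converged
                            else "fit did not converge; estimates unreliable")
    return tab


def _load_inputs(config: PipelineConfig):
    if config.preset is not None:
        presets = simulate_mod.preset_scenarios(
            n_patients=config.n_patients, seed=config.seed)
        if config.preset not in presets:
            raise InvalidArgumentError(
                f"unknown preset {config.preset!r}; have {sorted(presets)}")
        sim = presets[config.preset]
        cov, exposures, outcomes, confounders, truth = \
            simulate_mod.simulate_cohort(sim)
        return cov, exposures, outcomes, confounders, tuple(sim.classes)
    cov = read_covariates(config.covariates_csv)
    exposures = read_exposure_records(config.exposures_csv)
    outcomes = read_outcomes(config.outcomes_csv)
    return cov, exposures, outcomes, None, tuple(config.catalogue)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the three models independently; return (and write) the report."""
    config.validate()
    t0 = time.time()
    report: dict = {"config": config.resolved(),
                    "fingerprint": config.fingerprint(),
                    "stages": {}, "metadata": {}}

    cov_raw, exposures, outcomes, confounders, catalogue = _load_inputs(config)
    scheme = build_interval_scheme(config.window_start, config.window_end,
                                   config.n_intervals)
    design = encode_exposures(exposures, scheme, catalogue,
                              coding=config.coding,
                              patients=sorted(outcomes["patient_id"]))
    cov_raw = cov_raw.loc[design.patients]
    covariates = covariate_model_matrix(cov_raw)
    report["stages"]["encode"] = {
        "status": "ok", "n_patients": len(design.patients),
        "n_exposure_columns": design.n_columns,
        "n_covariate_terms": covariates.shape[1],
        "n_dropped_records": design.n_dropped_records}

    if config.restrict_terms:
        from .exposure import drop_column
        keep = set(config.restrict_terms)
        for lab in list(design.column_labels):
            if lab not in keep:
                design = drop_column(design, lab)

    # ---- Model 1: time-dependent competing-risk hazard model -------------
    model1_design = design
    try:
        model1_design, sep_log = selection_mod.resolve_separation(
            design, outcomes, horizon=config.horizon)
        if config.select:
            fit1, trace, final_cols = selection_mod.backward_eliminate(
                model1_design, outcomes, covariates, horizon=config.horizon,
                ties=config.ties)
        else:
            expansion = expand_counting_process(
                model1_design, covariates, outcomes, horizon=config.horizon)
            fit1 = fit_td_hazard(
                expansion, model1_design.column_labels
                + list(covariates.columns), ties=config.ties)
            trace, final_cols = None, model1_design.columns
        vif = None
        if fit1.n_terms >= 2 and fit1.n_rows > fit1.n_terms:
            expansion = expand_counting_process(
                model1_design, covariates, outcomes, horizon=config.horizon)
            present = [t for t in fit1.terms if t in expansion.columns]
            if len(present) >= 2:
                vif = compute_vif(expansion, present)
        report["stages"]["model1"] = {
            "status": "ok",
            "hr_table": render_hr_table(fit1).to_dict("records"),
            "fit": fit1.to_dict(),
            "separation_actions": sep_log,
            "selection": trace.to_dict() if trace else None,
            "significant_antibiotic_terms":
                selection_mod.significant_antibiotic_terms(fit1, final_cols),
            "vif": vif.to_dict() if vif is not None else None}
    except Exception as exc:
        logger.exception("model 1 failed")
        report["stages"]["model1"] = {"status": "error", "message": str(exc)}

    # ---- Model 2: marginal structural model ------------------------------
    try:
        models, person_days = msm_mod.fit_treatment_models(
            model1_design, outcomes, covariates,
            confounder_paths=confounders if confounders is not None
            and len(confounders) else None, horizon=config.horizon)
        ws = msm_mod.stabilized_weights(models, model1_design, person_days)
        if config.msm_truncate_percentiles:
            lo, hi = config.msm_truncate_percentiles
            ws = ws.truncate(lo, hi)
        expansion = expand_counting_process(
            model1_design, covariates, outcomes, horizon=config.horizon)
        fit2 = msm_mod.fit_msm(
            expansion, ws,
            model1_design.column_labels + list(covariates.columns),
            ties=config.ties)
        report["stages"]["model2"] = {
            "status": "ok",
            "hr_table": render_hr_table(fit2).to_dict("records"),
            "fit": fit2.to_dict(),
            "weight_diagnostics": ws.diagnostics()}
    except Exception as exc:
        logger.exception("model 2 failed")
        report["stages"]["model2"] = {"status": "error", "message": str(exc)}

    # ---- Model 3: Boruta -------------------------------------------------
    try:
        X, y = boruta_mod.build_feature_matrix(design, covariates, outcomes,
                                               horizon=config.horizon)
        res = boruta_mod.run_boruta(
            X, y, n_iter=config.boruta_iterations,
            rf_config={"n_estimators": config.boruta_trees},
            seed=config.seed)
        report["stages"]["model3"] = {
            "status": "ok",
            "decisions": res.decisions,
            "hit_counts": res.hit_counts,
            "z_scores": res.z_scores,
            "n_iterations": res.n_completed_iterations,
            "important": res.important()}
    except Exception as exc:
        logger.exception("model 3 failed")
        report["stages"]["model3"] = {"status": "error", "message": str(exc)}

    report["metadata"]["elapsed_seconds"] = round(time.time() - t0, 3)
    if config.out_dir:
        out = pathlib.Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = report.pop("metadata")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        for stage in ("model1", "model2"):
            block = report["stages"].get(stage, {})
            if block.get("status") == "ok":
                pd.DataFrame(block["hr_table"]).to_csv(
                    out / f"{stage}_hr_table.csv", index=False)
        report["metadata"] = meta
    return report
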