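"""Seeded generator of allo-HCT-like cohorts with known ground truth.

The generator walks integer days and emulates the statistical structure the
three models assume:

* baseline covariates drawn from declared level frequencies, plus neutrophil
  engraftment times (lognormal around a median of 17 days; a small fraction
  never engraft);
* a daily antibiotic treatment process: each class still uneligible in the
  current interval initiates with a logistic probability depending on the
  previous day's exposure status, baseline covariates, and (optionally) a
  time-varying illness ("fever") confounder with Markov dynamics;
* cause-specific hazards: a piecewise-constant (weekly) baseline aGVHD
  hazard multiplied by exp(true log-HR) for every active class-interval
  exposure (persistent coding) and by any confounder effect; a constant
  competing death hazard; daily event probabilities via 1 - exp(-h);
* administrative censoring at the horizon (day 180); there is no random
  loss to follow-up, mirroring a registry cohort with complete follow-up.

Outputs use the same schemas as real inputs (long administration records,
baseline covariate table, outcome table), so everything downstream is
exercised end-to-end; the truth used is recorded for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exposure import (DEFAULT_CATALOGUE, InvalidArgumentError,
                       build_interval_scheme, validate_catalogue)

#: Default weekly baseline daily hazards of aGVHD from day 0 (last value
#: extends to the horizon).  Chosen so that, with no exposure effects, the
#: cumulative incidence by day 180 sits in the 60-80% range with onset
#: median around four weeks, emulating a high-incidence transplant center.
DEFAULT_BASE_HAZARD_WEEKLY = (0.007, 0.011, 0.020, 0.024, 0.022, 0.017,
                              0.011, 0.007, 0.003)

DEFAULT_COVARIATE_FREQS = {
    "graft_source": {"pbsc": 0.75, "bone_marrow": 0.20, "cord_blood": 0.05},
    "conditioning_intensity": {"myeloablative": 0.55, "reduced_intensity": 0.45},
    "atg_use": {"no": 0.85, "yes": 0.15},
    "donor_type": {"related": 0.40, "unrelated": 0.60},
    "gvhd_prophylaxis": {"cni_based": 0.70, "ptcy_based": 0.30},
}


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 2023
    seed: int = 0
    classes: tuple = DEFAULT_CATALOGUE
    window_start: int = -7
    window_end: int = 30
    n_intervals: int = 5
    horizon: int = 180
    covariate_freqs: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_COVARIATE_FREQS.items()})
    # treatment process (daily logistic initiation model)
    treatment_intercept: float = -3.2
    prev_day_effect: float = 1.5          # same-class exposure on previous day
    baseline_treatment_effects: dict = field(default_factory=dict)
    confounder_treatment_effect: float = 0.0
    # confounder (daily fever/illness indicator, Markov chain)
    confounder_p_on: float = 0.05
    confounder_p_stay: float = 0.70
    confounder_hazard_effect: float = 0.0     # log scale, aGVHD hazard
    # outcome hazards
    true_log_hr: dict = field(default_factory=dict)  # {(class, interval): beta}
    base_hazard_weekly: tuple = DEFAULT_BASE_HAZARD_WEEKLY
    death_hazard: float = 0.0006
    # engraftment
    p_engraft: float = 0.98
    engraftment_log_median: float = float(np.log(17.0))
    engraftment_log_sd: float = 0.20

    def validate(self) -> None:
        problems = []
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.horizon <= 0:
            problems.append("horizon must be > 0")
        if any(h <= 0 for h in self.base_hazard_weekly):
            problems.append("base_hazard_weekly entries must be > 0")
        if self.death_hazard < 0:
            problems.append("death_hazard must be >= 0")
        for name, freqs in self.covariate_freqs.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                problems.append(f"frequencies for {name!r} must sum to 1")
        try:
            validate_catalogue(self.classes)
        except InvalidArgumentError as exc:
            problems.append(str(exc))
        if problems:
            raise InvalidArgumentError("invalid SimConfig: " + "; ".join(problems))

    @property
    def scheme(self):
        return build_interval_scheme(self.window_start, self.window_end,
                                     self.n_intervals)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classes"] = list(self.classes)
        d["base_hazard_weekly"] = list(self.base_hazard_weekly)
        d["true_log_hr"] = {f"{c}__{k}": v
                            for (c, k), v in self.true_log_hr.items()}
        return d


@dataclass
class SimTruth:
    """The effect map and treatment-process coefficients actually used."""

    true_log_hr: dict                # {"class__interval": beta}
    treatment_intercept: float
    prev_day_effect: float
    confounder_treatment_effect: float
    confounder_hazard_effect: float
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _base_hazard(day: int, weekly) -> float:
    if day < 0:
        return 0.0
    return weekly[min(day // 7, len(weekly) - 1)]


def simulate_cohort(config: SimConfig):
    """Generate one cohort: (covariates, exposure records, outcomes, truth).

    Deterministic given the config (byte-identical outputs for identical
    seeds).  Patients are walked day by day from the exposure-window start;
    within a day the order is confounder update, treatment decisions, then
    event sampling (so a same-day exposure already acts on the hazard).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    scheme = config.scheme
    classes = list(config.classes)
    n_cls, n_int = len(classes), scheme.n_intervals
    pids = [f"P{i:05d}" for i in range(n)]

    # baseline covariates
    cov = pd.DataFrame(index=pd.Index(pids, name="patient_id"))
    for name, freqs in config.covariate_freqs.items():
        levels = list(freqs)
        cov[name] = rng.choice(levels, size=n, p=[freqs[l] for l in levels])
    engrafted = rng.random(n) < config.p_engraft
    eday = np.round(np.exp(rng.normal(config.engraftment_log_median,
                                      config.engraftment_log_sd, n)))
    eday = np.clip(eday, 5, 60)
    cov["engrafted"] = engrafted
    cov["engraftment_day"] = np.where(engrafted, eday, np.nan)

    base_treat = np.zeros(n)
    for col, eff in config.baseline_treatment_effects.items():
        name, _, level = col.partition("=")
        base_treat += eff * (cov[name].astype(str) == level).to_numpy()

    beta = np.zeros((n_cls, n_int))
    for (c, k), b in config.true_log_hr.items():
        if c not in classes:
            raise InvalidArgumentError(f"true_log_hr class {c!r} not simulated")
        beta[classes.index(c), k] = b

    first_day = np.full((n, n_cls, n_int), np.nan)
    conf = np.zeros(n, dtype=bool)
    at_risk = np.ones(n, dtype=bool)
    event_day = np.full(n, config.horizon, dtype=int)
    event_type = np.array(["censored"] * n, dtype=object)
    records: list[tuple] = []
    conf_rows: list[tuple] = []

    for day in range(config.window_start, config.horizon + 1):
        if not at_risk.any():
            break
        u = rng.random(n)
        if day <= scheme.window_end:
            # peri-transplant illness process; frozen (carried forward) once
            # the exposure window closes
            conf = np.where(conf, u < config.confounder_p_stay,
                            u < config.confounder_p_on)
        if config.confounder_treatment_effect != 0.0 or \
           config.confounder_hazard_effect != 0.0:
            for i in np.nonzero(at_risk & conf)[0]:
                conf_rows.append((pids[i], day, 1.0))

        if scheme.window_start <= day <= scheme.window_end:
            k = scheme.interval_of(day)
            for ci in range(n_cls):
                prev_same = np.nanmin(
                    np.where(np.isnan(first_day[:, ci, :]), np.inf,
                             first_day[:, ci, :]), axis=1) <= day - 1
                eligible = at_risk & np.isnan(first_day[:, ci, k])
                eta = (config.treatment_intercept
                       + config.prev_day_effect * prev_same
                       + base_treat
                       + config.confounder_treatment_effect * conf)
                p_init = 1.0 / (1.0 + np.exp(-eta))
                draws = rng.random(n)
                init = eligible & (draws < p_init)
                for i in np.nonzero(init)[0]:
                    first_day[i, ci, k] = day
                    records.append((pids[i], day, classes[ci]))

        if day >= 0:
            h0 = _base_hazard(day, config.base_hazard_weekly)
            active = (~np.isnan(first_day)) & (first_day <= day)
            log_mult = np.sum(active * beta[None, :, :], axis=(1, 2))
            log_mult += config.confounder_hazard_effect * conf
            h_a = h0 * np.exp(log_mult)
            h_d = np.full(n, config.death_hazard)
            h_tot = h_a + h_d
            p_event = 1.0 - np.exp(-h_tot)
            u1 = rng.random(n)
            u2 = rng.random(n)
            hit = at_risk & (u1 < p_event)
            with np.errstate(invalid="ignore", divide="ignore"):
                is_agvhd = u2 < np.where(h_tot > 0, h_a / h_tot, 0.0)
            for i in np.nonzero(hit)[0]:
                event_day[i] = day
                event_type[i] = "agvhd" if is_agvhd[i] else "death"
            at_risk &= ~hit

    exposures = pd.DataFrame(records,
                             columns=["patient_id", "day", "abx_class"])
    outcomes = pd.DataFrame({"patient_id": pids, "event_day": event_day,
                             "event_type": event_type})
    confounders = pd.DataFrame(conf_rows,
                               columns=["patient_id", "day", "value"])
    truth = SimTruth(
        true_log_hr={f"{c}__{k}": v for (c, k), v in config.true_log_hr.items()},
        treatment_intercept=config.treatment_intercept,
        prev_day_effect=config.prev_day_effect,
        confounder_treatment_effect=config.confounder_treatment_effect,
        confounder_hazard_effect=config.confounder_hazard_effect,
        config=config.to_dict())
    return cov, exposures, outcomes, confounders, truth


RECOVERY_CLASSES = ("carbapenems", "fluoroquinolones", "vancomycin_iv")


def preset_scenarios(n_patients: int | None = None,
                     seed: int | None = None) -> dict[str, SimConfig]:
    """Named simulation scenarios with documented ground truth.

    * ``null`` — full catalogue, no exposure effects, no confounding.
    * ``confounded_null`` — a daily illness indicator raises both the
      initiation probability and the aGVHD hazard while every true exposure
      HR is 1, so the unweighted estimator is biased and the MSM is not.
    * ``carbapenem_week1`` — one true HR of 2.75 on carbapenems in the first
      post-transplant week and randomized-style treatment (history dependence
      only), for clean parameter recovery.  The competing death hazard is
      zero here so the subdistribution and cause-specific estimands coincide
      and the generating log-HR is the exact truth for the fitted model;
      competing death is exercised by the other scenarios.
    * ``multi_effect`` — several nonzero HRs with measured confounding.
    """
    presets = {
        "null": SimConfig(),
        "confounded_null": SimConfig(
            classes=RECOVERY_CLASSES,
            confounder_treatment_effect=1.5,
            confounder_hazard_effect=1.5,
            confounder_p_on=0.015,
            confounder_p_stay=1.0),
        "carbapenem_week1": SimConfig(
            classes=RECOVERY_CLASSES,
            true_log_hr={("carbapenems", 1): float(np.log(2.75))},
            death_hazard=0.0),
        "multi_effect": SimConfig(
            classes=RECOVERY_CLASSES + ("penicillins_bli",),
            true_log_hr={("carbapenems", 1): float(np.log(2.75)),
                         ("penicillins_bli", 1): float(np.log(2.0)),
                         ("fluoroquinolones", 4): float(np.log(1.8))},
            confounder_treatment_effect=1.0,
            confounder_hazard_effect=0.8,
            confounder_p_on=0.015,
            confounder_p_stay=1.0),
    }
    for cfg in presets.values():
        if n_patients is not None:
            cfg.n_patients = n_patients
        if seed is not None:
            cfg.seed = seed
    return presets


def write_cohort(out_dir, cov: pd.DataFrame, exposures: pd.DataFrame,
                 outcomes: pd.DataFrame, truth: SimTruth) -> None:
    """Write the three input CSVs plus the ground-truth JSON."""
    import pathlib
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cov.reset_index().to_csv(out / "covariates.csv", index=False)
    exposures.to_csv(out / "exposures.csv", index=False)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    truth.to_json(out / "sim_truth.json")
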