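"""Replicated simulation experiments over the three models.

Each experiment regenerates cohorts from the preset scenarios, runs the
relevant estimator from scratch, and summarizes the Monte-Carlo behaviour
(bias, coverage, selection survival, false-selection rates).  These
functions back both the test suite and the reproduction script; problem
sizes are arguments so callers can scale replicate counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boruta import run_boruta
from .exposure import encode_exposures
from .msm import fit_msm, fit_treatment_models, stabilized_weights
from .selection import backward_eliminate, resolve_separation
from .simulate import (RECOVERY_CLASSES, SimConfig, preset_scenarios,
                       simulate_cohort)
from .survival import expand_counting_process, fit_td_hazard


def _subseed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % 2**31)


def _encode(cfg, exposures, outcomes):
    return encode_exposures(exposures, cfg.scheme, cfg.classes,
                            patients=sorted(outcomes["patient_id"]))


def recovery_experiment(n_reps: int = 100, n_patients: int = 2023,
                        seed: int = 1) -> dict:
    """Parameter recovery of the single true HR in ``carbapenem_week1``.

    Fits the competing-risk hazard model per replicate and summarizes the
    estimate of the carbapenems / week-1 log-HR (truth log 2.75) and the
    empirical 95% CI coverage.
    """
    truth = float(np.log(2.75))
    betas, covers = [], []
    for r in range(n_reps):
        cfg = preset_scenarios(n_patients=n_patients,
                               seed=_subseed(seed, r))["carbapenem_week1"]
        _cov, exposures, outcomes, _conf, _ = simulate_cohort(cfg)
        design = _encode(cfg, exposures, outcomes)
        expansion = expand_counting_process(design, None, outcomes,
                                            fine_gray=True)
        fit = fit_td_hazard(expansion, design.column_labels)
        i = fit.term_index("carbapenems__1")
        betas.append(float(fit.coef[i]))
        covers.append(bool(fit.ci_low[i] <= 2.75 <= fit.ci_high[i]))
    b = np.asarray(betas)
    mcse = float(b.std(ddof=1) / np.sqrt(n_reps))
    return {"truth_log_hr": truth, "mean_beta": float(b.mean()),
            "mean_hr": float(np.exp(b.mean())), "mc_se": mcse,
            "z_vs_truth": float((b.mean() - truth) / mcse),
            "coverage": float(np.mean(covers)), "n_reps": n_reps,
            "n_patients": n_patients}


def confounding_experiment(n_batches: int = 10, reps_per_batch: int = 3,
                           n_patients: int = 500, seed: int = 1) -> dict:
    """Confounding correction in ``confounded_null`` (every true HR = 1).

    Per replicate, fits the unweighted hazard model and the stabilized-IPTW
    MSM with the illness confounder measured; the bias metric is the mean
    exposure coefficient (truth 0).  Batched comparison of absolute bias.
    """
    unw, msm = [], []
    n_reps = n_batches * reps_per_batch
    for r in range(n_reps):
        cfg = preset_scenarios(n_patients=n_patients,
                               seed=_subseed(seed, 10_000 + r))["confounded_null"]
        _cov, exposures, outcomes, conf, _ = simulate_cohort(cfg)
        design = _encode(cfg, exposures, outcomes)
        expansion = expand_counting_process(design, None, outcomes,
                                            fine_gray=True)
        f0 = fit_td_hazard(expansion, design.column_labels)
        models, pdt = fit_treatment_models(design, outcomes,
                                           confounder_paths=conf)
        ws = stabilized_weights(models, design, pdt)
        f1 = fit_msm(expansion, ws, design.column_labels, robust=False)
        unw.append(float(np.mean(f0.coef)))
        msm.append(float(np.mean(f1.coef)))
    u = np.asarray(unw).reshape(n_batches, reps_per_batch).mean(axis=1)
    m = np.asarray(msm).reshape(n_batches, reps_per_batch).mean(axis=1)
    better = int(np.sum(np.abs(m) < np.abs(u)))
    return {"mean_bias_unweighted": float(np.mean(unw)),
            "mean_bias_msm": float(np.mean(msm)),
            "batches_msm_better": better, "n_batches": n_batches,
            "reps_per_batch": reps_per_batch, "n_patients": n_patients}


def null_selection_experiment(n_reps: int = 50, n_patients: int = 150,
                              classes=RECOVERY_CLASSES, seed: int = 1) -> dict:
    """Backward elimination on effect-free cohorts.

    Reports the fraction of antibiotic classes surviving selection (a class
    survives if any of its terms remains in the final model) and whether the
    accepted-step AIC sequence was strictly decreasing in every replicate.
    """
    survived, total = 0, 0
    aic_monotone = True
    for r in range(n_reps):
        cfg = SimConfig(classes=tuple(classes), n_patients=n_patients,
                        seed=_subseed(seed, 20_000 + r))
        _cov, exposures, outcomes, _conf, _ = simulate_cohort(cfg)
        design = _encode(cfg, exposures, outcomes)
        design, _actions = resolve_separation(design, outcomes)
        fit, trace, cols = backward_eliminate(design, outcomes, None)
        aics = [trace.initial_fit.aic] + [s.aic_after
                                          for s in trace.accepted_steps]
        if any(b >= a for a, b in zip(aics, aics[1:])):
            aic_monotone = False
        survived += len({c.abx_class for c in cols})
        total += len(classes)
    return {"fraction_classes_surviving": survived / total,
            "aic_strictly_decreasing_all_reps": aic_monotone,
            "n_reps": n_reps, "n_patients": n_patients,
            "n_classes": len(classes)}


def boruta_null_experiment(n_seeds: int = 5, n_samples: int = 500,
                           n_features: int = 8, n_iter: int = 40,
                           n_trees: int = 100, seed: int = 1) -> dict:
    """False-selection control: outcome permuted against all features.

    The sample size matters here: chance feature-outcome correlations scale
    as 1/sqrt(n) and persist across iterations while shadows are re-shuffled,
    so false-selection control is a large-sample property.
    """
    zero_important = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(_subseed(seed, 30_000 + s))
        X = pd.DataFrame(rng.binomial(1, 0.4, (n_samples, n_features))
                         .astype(float),
                         columns=[f"f{i}" for i in range(n_features)])
        y = rng.permutation(rng.binomial(1, 0.5, n_samples))
        res = run_boruta(X, y, n_iter=n_iter,
                         rf_config={"n_estimators": n_trees},
                         seed=_subseed(seed, 40_000 + s))
        if not res.important():
            zero_important += 1
    return {"seeds_with_zero_important": zero_important,
            "n_seeds": n_seeds, "n_iter": n_iter, "n_samples": n_samples}


def boruta_signal_experiment(n_samples: int = 200, n_noise: int = 7,
                             n_iter: int = 40, n_trees: int = 100,
                             seed: int = 1) -> dict:
    """Positive control: a feature identical to the outcome must be selected."""
    rng = np.random.default_rng(_subseed(seed, 50_000))
    X = pd.DataFrame(rng.binomial(1, 0.4, (n_samples, n_noise)).astype(float),
                     columns=[f"noise{i}" for i in range(n_noise)])
    y = pd.Series(rng.binomial(1, 0.5, n_samples))
    X.insert(0, "signal", y.astype(float))
    res = run_boruta(X, y, n_iter=n_iter,
                     rf_config={"n_estimators": n_trees},
                     seed=_subseed(seed, 50_001))
    return {"signal_decision": res.decisions["signal"],
            "n_important": len(res.important()),
            "n_iter": res.n_completed_iterations}
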