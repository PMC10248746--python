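"""Treatment models, stabilized weights, and weighted MSM fits."""

import numpy as np
import pandas as pd
import pytest

from abxgvhd.exposure import build_interval_scheme, encode_exposures
from abxgvhd.msm import (PositivityError, cumulative_stabilized_weight,
                         fit_msm, fit_treatment_models, stabilized_weights)
from abxgvhd.simulate import SimConfig, simulate_cohort
from abxgvhd.survival import expand_counting_process, fit_td_hazard
from conftest import make_outcomes, make_records


def coin_flip_cohort(n=500, p=0.5, n_days=4, seed=0):
    """Exposure by independent daily fair coin; one class, one interval."""
    rng = np.random.default_rng(seed)
    scheme = build_interval_scheme(0, n_days - 1, 1)
    rows = []
    pids = [f"p{i}" for i in range(n)]
    for pid in pids:
        for d in range(n_days):
            if rng.random() < p:
                rows.append((pid, d, "carbapenems"))
                break
    rec = make_records(rows)
    design = encode_exposures(rec, scheme, ("carbapenems",), patients=pids)
    out = make_outcomes([(pid, 180, "censored") for pid in pids])
    return design, out


class TestTreatmentModels:
    def test_coin_flip_recovers_half(self):
        design, out = coin_flip_cohort(n=500)  # ~2000 person-days
        models, pdt = fit_treatment_models(design, out)
        num, den = models["carbapenems"]
        for m in (num, den):
            p = m.predict_proba(pdt[pdt.abx_class == "carbapenems"])
            assert np.mean(p) == pytest.approx(0.5, abs=0.03)

    def test_never_administered_class_skipped(self, scheme):
        rec = make_records([("a", 3, "carbapenems")])
        design = encode_exposures(rec, scheme,
                                  ("carbapenems", "fluoroquinolones"),
                                  patients=["a", "b"])
        out = make_outcomes([("a", 180, "censored"), ("b", 180, "censored")])
        models, pdt = fit_treatment_models(design, out)
        assert models["fluoroquinolones"] is None
        ws = stabilized_weights(models, design, pdt)
        assert np.all(np.isfinite(ws.frame.to_numpy()))

    def test_no_covariates_numerator_equals_denominator(self):
        design, out = coin_flip_cohort(n=120)
        models, _ = fit_treatment_models(design, out)
        num, den = models["carbapenems"]
        assert num.predictors == den.predictors
        assert np.allclose(num.params, den.params)


class TestStabilizedWeights:
    def test_hand_product_of_ratios(self):
        # exposed on both decision days; denominator (0.5, 0.8),
        # numerator (0.6, 0.7) -> sw = (0.6/0.5)*(0.7/0.8) = 1.05
        assert cumulative_stabilized_weight([0.6, 0.7], [0.5, 0.8]) \
            == pytest.approx(1.05, abs=1e-12)

    def test_positivity_violation_raises(self):
        with pytest.raises(PositivityError):
            cumulative_stabilized_weight([0.5], [1.0])

    def test_identical_models_give_unit_weights(self):
        design, out = coin_flip_cohort(n=150)
        models, pdt = fit_treatment_models(design, out)
        ws = stabilized_weights(models, design, pdt)
        assert np.all(ws.frame.to_numpy() == 1.0)

    def test_randomized_exposure_mean_weight_near_one(self, covariate_table):
        # denominator includes baseline covariates that truly play no role
        cfg = SimConfig(classes=("carbapenems", "fluoroquinolones"),
                        n_patients=500, seed=9)
        cov, exposures, outcomes, _conf, _ = simulate_cohort(cfg)
        from abxgvhd.survival import covariate_model_matrix
        X = covariate_model_matrix(cov)
        design = encode_exposures(exposures, cfg.scheme, cfg.classes,
                                  patients=sorted(outcomes.patient_id))
        models, pdt = fit_treatment_models(design, outcomes, covariates=X)
        ws = stabilized_weights(models, design, pdt)
        assert ws.diagnostics()["mean"] == pytest.approx(1.0, abs=0.05)

    def test_weights_invariant_to_patient_relabeling(self):
        design, out = coin_flip_cohort(n=80, seed=3)
        models, pdt = fit_treatment_models(design, out)
        ws1 = stabilized_weights(models, design, pdt)
        # relabel and reorder the person-day table
        perm = {p: f"q{i:03d}" for i, p in enumerate(design.patients)}
        design2 = design.copy()
        design2.patients = [perm[p] for p in design.patients]
        design2.first_day = design.first_day.rename(index=perm)
        pdt2 = pdt.assign(patient_id=pdt.patient_id.map(perm)) \
                  .sample(frac=1, random_state=0)
        out2 = out.assign(patient_id=out.patient_id.map(perm))
        models2, pdt2 = fit_treatment_models(design2, out2,
                                             person_days=pdt2)
        ws2 = stabilized_weights(models2, design2, pdt2)
        for p in design.patients:
            assert ws1.frame.loc[p].to_numpy() == pytest.approx(
                ws2.frame.loc[perm[p]].to_numpy(), abs=1e-10)

    def test_diagnostics_recomputed_exactly(self):
        design, out = coin_flip_cohort(n=60, seed=2)
        models, pdt = fit_treatment_models(design, out)
        ws = stabilized_weights(models, design, pdt)
        d = ws.diagnostics()
        vals = ws.frame.to_numpy().ravel()
        assert d["min"] == vals.min() and d["max"] == vals.max()
        assert d["mean"] == pytest.approx(vals.mean())


class TestWeightedFit:
    def test_unit_weights_reproduce_unweighted_fit(self, scheme):
        rec = make_records([("a", 3, "carbapenems"), ("b", 5, "carbapenems")])
        design = encode_exposures(rec, scheme, ("carbapenems",),
                                  patients=["a", "b", "c", "d"])
        out = make_outcomes([("a", 40, "agvhd"), ("b", 120, "censored"),
                             ("c", 60, "agvhd"), ("d", 90, "agvhd")])
        expansion = expand_counting_process(design, None, out)
        models, pdt = fit_treatment_models(design, out)
        ws = stabilized_weights(models, design, pdt)
        assert np.all(ws.frame.to_numpy() == 1.0)
        f_w = fit_msm(expansion, ws, ["carbapenems__1"], robust=False)
        f_u = fit_td_hazard(expansion, ["carbapenems__1"])
        assert f_w.coef[0] == f_u.coef[0]
        assert f_w.log_likelihood == f_u.log_likelihood
        assert f_w.aic == f_u.aic

    def test_robust_se_differs_from_naive(self, scheme):
        rec = make_records([("a", 3, "carbapenems"), ("b", 5, "carbapenems")])
        design = encode_exposures(rec, scheme, ("carbapenems",),
                                  patients=["a", "b", "c", "d"])
        out = make_outcomes([("a", 40, "agvhd"), ("b", 120, "censored"),
                             ("c", 60, "agvhd"), ("d", 90, "agvhd")])
        expansion = expand_counting_process(design, None, out)
        f_r = fit_msm(expansion, None, ["carbapenems__1"], robust=True)
        f_n = fit_td_hazard(expansion, ["carbapenems__1"])
        assert f_r.robust and not f_n.robust
        assert f_r.coef[0] == pytest.approx(f_n.coef[0], abs=1e-12)
        assert f_r.se[0] != pytest.approx(f_n.se[0], abs=1e-12)
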