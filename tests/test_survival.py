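"""Partial-likelihood engine, Fine-Gray IPCW, and diagnostics.

The fitter is checked against independent oracles: a hand-written partial
likelihood maximized by grid search on tiny fixtures, a hand-enumerated
Kaplan-Meier of the censoring distribution, and lifelines'
CoxTimeVaryingFitter on a random untied fixture.
"""

import numpy as np
import pandas as pd
import pytest

from abxgvhd.exposure import InvalidArgumentError, encode_exposures
from abxgvhd.survival import (SeparationError, censoring_survival,
                              compute_vif, covariate_model_matrix,
                              engraftment_covariates,
                              expand_counting_process, fine_gray_ipcw,
                              fit_td_hazard)
from conftest import make_outcomes, make_records


def rows_frame(rows):
    """(patient, start, stop, event, x, w) -> counting-process frame."""
    return pd.DataFrame(rows, columns=["patient_id", "start", "stop",
                                       "event", "x", "w"])


def hand_log_partial_likelihood(df, betas):
    """Weighted partial log-likelihood for untied right-censored rows,
    written directly from the definition (risk set = stop >= event time);
    evaluated over an array of beta values."""
    betas = np.atleast_1d(betas)
    ll = np.zeros(len(betas))
    for _, ev in df[df.event == 1].iterrows():
        at_risk = df[(df.start < ev.stop) & (df.stop >= ev.stop)]
        denom = np.sum(at_risk.w.to_numpy()[:, None]
                       * np.exp(np.outer(at_risk.x.to_numpy(), betas)), axis=0)
        ll += ev.w * (ev.x * betas - np.log(denom))
    return ll


class TestEngraftment:
    def test_all_engrafted(self, covariate_table):
        sub = covariate_table.iloc[:3]
        e = engraftment_covariates(sub)
        assert e["non_engrafted"].tolist() == [0, 0, 0]
        assert e["days_to_engraftment"].tolist() == [14.0, 17.0, 20.0]

    def test_median_imputation_for_non_engrafter(self, covariate_table):
        sub = covariate_table.loc[["p0", "p2", "p5"]]  # days 14, 20, absent
        e = engraftment_covariates(sub)
        assert e.loc["p5", "non_engrafted"] == 1
        assert e.loc["p5", "days_to_engraftment"] == 17.0

    def test_no_engrafters_is_error(self, covariate_table):
        sub = covariate_table.loc[["p5"]]
        with pytest.raises(InvalidArgumentError):
            engraftment_covariates(sub)

    def test_model_matrix_has_nine_terms(self, covariate_table):
        X = covariate_model_matrix(covariate_table)
        assert X.shape[1] == 9
        assert "donor_x_prophylaxis" in X.columns


class TestExpansion:
    def test_unexposed_patient_single_row(self, simple_design):
        out = make_outcomes([("a", 40, "agvhd"), ("b", 180, "censored"),
                             ("c", 40, "agvhd")])
        e = expand_counting_process(simple_design, None, out, fine_gray=False)
        c_rows = e[e.patient_id == "c"]
        assert len(c_rows) == 1
        assert (c_rows.start.iloc[0], c_rows.stop.iloc[0]) == (-7, 40)
        assert c_rows.event.iloc[0] == 1

    def test_switch_breaks_follow_up(self, simple_design):
        out = make_outcomes([("a", 180, "censored"), ("b", 180, "censored"),
                             ("c", 180, "censored")])
        e = expand_counting_process(simple_design, None, out, fine_gray=False)
        a_rows = e[e.patient_id == "a"].sort_values("start")
        assert [(r.start, r.stop) for r in a_rows.itertuples()] == \
            [(-7, 2), (3, 180)]
        assert a_rows["carbapenems__1"].tolist() == [0.0, 1.0]

    def test_row_count_is_one_plus_switch_days(self, scheme):
        rec = make_records([("a", 3, "carbapenems"), ("a", 3, "fluoroquinolones"),
                            ("a", 10, "carbapenems")])
        d = encode_exposures(rec, scheme, ("carbapenems", "fluoroquinolones"))
        out = make_outcomes([("a", 180, "censored")])
        e = expand_counting_process(d, None, out, fine_gray=False)
        assert len(e) == 1 + 2  # switch days {3, 10}

    def test_missing_outcome_names_patient(self, simple_design):
        out = make_outcomes([("a", 40, "agvhd"), ("b", 180, "censored")])
        with pytest.raises(InvalidArgumentError, match="c"):
            expand_counting_process(simple_design, None, out)


class TestIPCW:
    def test_no_competing_events_no_extension(self):
        out = make_outcomes([("a", 30, "agvhd"), ("b", 100, "censored")])
        assert fine_gray_ipcw(out).empty

    def test_no_censoring_weights_all_one(self):
        # administrative horizon censoring only happens beyond day 180
        out = make_outcomes([("a", 10, "death"), ("b", 30, "agvhd"),
                             ("c", 60, "agvhd")])
        w = fine_gray_ipcw(out)
        assert np.allclose(w["weight"], 1.0)

    def test_hand_kaplan_meier_weights(self):
        # A dies d10; B censored d20; D event d15; C event d30.
        # Censoring KM: G(d)=1 for d<20; at d=20 risk={B,C}, 1 censored
        # -> G = 0.5 for d>=20.  A's extension weights: day 15 ->
        # G(14)/G(9)=1; day 30 -> G(29)/G(9)=0.5.
        out = make_outcomes([("a", 10, "death"), ("b", 20, "censored"),
                             ("c", 30, "agvhd"), ("d", 15, "agvhd")])
        w = fine_gray_ipcw(out).set_index("day")["weight"]
        assert w.loc[15] == pytest.approx(1.0)
        assert w.loc[30] == pytest.approx(0.5)

    def test_censoring_survival_step_values(self):
        out = make_outcomes([("a", 10, "death"), ("b", 20, "censored"),
                             ("c", 30, "agvhd"), ("d", 15, "agvhd")])
        G = censoring_survival(out)
        assert G(19) == pytest.approx(1.0)
        assert G(20) == pytest.approx(0.5)


class TestFitter:
    def test_null_loglik_two_patients(self):
        df = rows_frame([("a", 0, 5, 1, 0.0, 1.0), ("b", 0, 10, 0, 0.0, 1.0)])
        fit = fit_td_hazard(df, [])
        assert fit.log_likelihood == pytest.approx(-np.log(2), abs=1e-12)
        assert fit.aic == pytest.approx(2 * np.log(2), abs=1e-12)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_grid_search_oracle_six_patients(self, weighted):
        w = [1.3, 0.7, 2.0, 1.0, 0.5, 1.4] if weighted else [1.0] * 6
        df = rows_frame([
            ("a", 0, 3, 1, 1.0, w[0]), ("b", 0, 5, 1, 0.0, w[1]),
            ("c", 0, 7, 0, 1.0, w[2]), ("d", 0, 9, 1, 1.0, w[3]),
            ("e", 0, 11, 1, 0.0, w[4]), ("f", 0, 13, 0, 0.0, w[5])])
        grid = np.arange(-3, 3, 1e-4)
        lls = hand_log_partial_likelihood(df, grid)
        beta_grid = grid[int(np.argmax(lls))]
        fit = fit_td_hazard(df, ["x"], weights=df["w"].to_numpy())
        assert fit.coef[0] == pytest.approx(beta_grid, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(float(np.max(lls)),
                                                   abs=1e-6)

    def test_weight_scale_invariance(self):
        df = rows_frame([("a", 0, 3, 1, 1.0, 1.0), ("b", 0, 5, 1, 0.0, 1.0),
                         ("c", 0, 7, 0, 1.0, 1.0), ("d", 0, 9, 1, 1.0, 1.0)])
        f1 = fit_td_hazard(df, ["x"], weights=np.ones(4))
        f2 = fit_td_hazard(df, ["x"], weights=np.full(4, 7.0))
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-10)

    def test_score_norm_small_at_optimum(self):
        rng = np.random.default_rng(4)
        n = 50
        df = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)], "start": 0,
            "stop": rng.integers(1, 40, n) + rng.random(n),
            "event": rng.binomial(1, 0.6, n),
            "x": rng.normal(size=n)})
        fit = fit_td_hazard(df, ["x"])
        from abxgvhd.survival import _loglik_parts
        _, U, _, _, _ = _loglik_parts(
            fit.coef, df[["x"]].to_numpy(), np.ones(n),
            df["start"].to_numpy(float), df["stop"].to_numpy(float),
            df["event"].to_numpy(int),
            np.unique(df.loc[df.event == 1, "stop"]))
        assert np.max(np.abs(U)) < 1e-7

    def test_matches_lifelines_time_varying(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        rows = []
        for i in range(40):
            # two rows per patient: covariate switch mid-follow-up
            switch = int(rng.integers(2, 10))
            stop = switch + int(rng.integers(1, 30)) + float(rng.random())
            x0, x1 = rng.normal(size=2)
            ev = int(rng.binomial(1, 0.6))
            rows.append((f"p{i}", 0, switch, 0, x0))
            rows.append((f"p{i}", switch, stop, ev, x1))
        df = pd.DataFrame(rows, columns=["patient_id", "start", "stop",
                                         "event", "x"])
        fit = fit_td_hazard(df, ["x"])
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(df.rename(columns={"patient_id": "id"}), id_col="id",
                start_col="start", stop_col="stop", event_col="event")
        assert fit.coef[0] == pytest.approx(ctv.params_.iloc[0], abs=1e-4)
        assert fit.se[0] == pytest.approx(
            ctv.standard_errors_.iloc[0], abs=1e-4)

    def test_efron_and_breslow_differ_on_ties(self):
        df = rows_frame([("a", 0, 5, 1, 1.0, 1.0), ("b", 0, 5, 1, 0.0, 1.0),
                         ("c", 0, 9, 1, 1.0, 1.0), ("d", 0, 11, 0, 0.0, 1.0)])
        fe = fit_td_hazard(df, ["x"], ties="efron")
        fb = fit_td_hazard(df, ["x"], ties="breslow")
        assert fe.log_likelihood != pytest.approx(fb.log_likelihood, abs=1e-6)

    def test_separation_raises_naming_term(self):
        # x perfectly predicts the events
        df = rows_frame([("a", 0, 3, 1, 1.0, 1.0), ("b", 0, 5, 1, 1.0, 1.0),
                         ("c", 0, 7, 0, 0.0, 1.0), ("d", 0, 9, 0, 0.0, 1.0)])
        with pytest.raises(SeparationError, match="x"):
            fit_td_hazard(df, ["x"])

    def test_degenerate_column_dropped(self):
        df = rows_frame([("a", 0, 3, 1, 1.0, 1.0), ("b", 0, 5, 1, 0.0, 1.0),
                         ("c", 0, 7, 0, 1.0, 1.0)])
        df["const"] = 1.0
        fit = fit_td_hazard(df, ["x", "const"])
        assert fit.dropped_terms == ["const"]
        assert fit.terms == ["x"]

    def test_hazard_ratio_is_exp_coef(self):
        df = rows_frame([("a", 0, 3, 1, 1.0, 1.0), ("b", 0, 5, 1, 0.0, 1.0),
                         ("c", 0, 7, 0, 1.0, 1.0), ("d", 0, 9, 1, 0.0, 1.0)])
        fit = fit_td_hazard(df, ["x"])
        assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_low[0] < fit.hazard_ratios[0] < fit.ci_high[0]


class TestFineGrayEquivalence:
    def test_zero_competing_fits_identical(self, scheme, tiny_catalogue):
        rec = make_records([("a", 3, "carbapenems"), ("b", 5, "carbapenems")])
        design = encode_exposures(rec, scheme, tiny_catalogue,
                                  patients=["a", "b", "c"])
        out = make_outcomes([("a", 40, "agvhd"), ("b", 120, "censored"),
                             ("c", 60, "agvhd")])
        e_fg = expand_counting_process(design, None, out, fine_gray=True)
        e_cs = expand_counting_process(design, None, out, fine_gray=False)
        pd.testing.assert_frame_equal(e_fg, e_cs)
        f_fg = fit_td_hazard(e_fg, ["carbapenems__1"])
        f_cs = fit_td_hazard(e_cs, ["carbapenems__1"])
        assert abs(f_fg.coef[0] - f_cs.coef[0]) < 1e-8

    def test_competing_event_patient_extended(self, simple_design):
        out = make_outcomes([("a", 40, "agvhd"), ("b", 20, "death"),
                             ("c", 120, "agvhd")])
        e = expand_counting_process(simple_design, None, out, fine_gray=True)
        b_rows = e[e.patient_id == "b"]
        # extended on primary event days after day 20: day 40 and day 120
        assert set(b_rows.stop) >= {40, 120}


class TestVIF:
    def test_orthogonal_columns_vif_one(self):
        df = pd.DataFrame({"a": [1, 1, 0, 0.], "b": [1, 0, 1, 0.]})
        v = compute_vif(df, ["a", "b"])
        assert np.allclose(v, 1.0)

    def test_duplicated_column_infinite(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4.], "b": [1, 2, 3, 4.],
                           "c": [0, 1, 0, 1.]})
        v = compute_vif(df, ["a", "b", "c"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_r2_075_gives_vif_4(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        u = np.array([1.0, 1.0, -1.0, -1.0])
        z = np.sqrt(3.0) * x + u          # corr(x, z)^2 = 3/4 exactly
        df = pd.DataFrame({"x": x, "z": z})
        v = compute_vif(df, ["x", "z"])
        assert v["x"] == pytest.approx(4.0, rel=1e-9)
        assert v["z"] == pytest.approx(4.0, rel=1e-9)
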