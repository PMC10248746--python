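"""Perfect-separation handling and AIC-guided backward elimination."""

import numpy as np
import pytest

from abxgvhd.exposure import (InvalidArgumentError, build_interval_scheme,
                              encode_exposures)
from abxgvhd.selection import (SelectionStep, backward_eliminate,
                               detect_perfect_separation, resolve_separation)
from abxgvhd.simulate import SimConfig, simulate_cohort
from conftest import make_outcomes, make_records


def design_with(records, patients, scheme, catalogue=("carbapenems",
                                                      "fluoroquinolones")):
    return encode_exposures(make_records(records), scheme, catalogue,
                            patients=patients)


class TestDetect:
    def test_all_exposed_with_event_flagged(self, scheme):
        d = design_with([("a", 3, "carbapenems"), ("b", 4, "carbapenems"),
                         ("c", 5, "carbapenems")], ["a", "b", "c", "x"],
                        scheme)
        out = make_outcomes([("a", 40, "agvhd"), ("b", 50, "agvhd"),
                             ("c", 60, "agvhd"), ("x", 180, "censored")])
        assert "carbapenems__1" in detect_perfect_separation(d, out)

    def test_mixed_outcomes_not_flagged(self, scheme):
        d = design_with([("a", 3, "carbapenems"), ("b", 4, "carbapenems"),
                         ("c", 5, "carbapenems")], ["a", "b", "c"], scheme)
        out = make_outcomes([("a", 40, "agvhd"), ("b", 50, "agvhd"),
                             ("c", 180, "censored")])
        assert detect_perfect_separation(d, out) == []

    def test_zero_exposed_not_flagged(self, scheme):
        d = design_with([], ["a", "b"], scheme)
        out = make_outcomes([("a", 40, "agvhd"), ("b", 180, "censored")])
        assert detect_perfect_separation(d, out) == []


class TestResolve:
    def test_merges_with_earlier_adjacent_interval(self, scheme):
        # separation in interval 2 only; interval 1 has mixed outcomes
        d = design_with([("a", 8, "carbapenems"),          # interval 2, event
                         ("b", 3, "carbapenems"),          # interval 1, event
                         ("c", 4, "carbapenems")],         # interval 1, censored
                        ["a", "b", "c", "x"], scheme)
        out = make_outcomes([("a", 40, "agvhd"), ("b", 50, "agvhd"),
                             ("c", 180, "censored"), ("x", 60, "agvhd")])
        resolved, actions = resolve_separation(d, out)
        assert actions == [{"action": "merge", "abx_class": "carbapenems",
                            "interval_indices": [1, 2]}]
        assert "carbapenems__1-2" in resolved.column_labels
        assert detect_perfect_separation(resolved, out) == []

    def test_clean_design_unchanged(self, scheme):
        d = design_with([("a", 3, "carbapenems"), ("b", 4, "carbapenems")],
                        ["a", "b"], scheme)
        out = make_outcomes([("a", 40, "agvhd"), ("b", 180, "censored")])
        resolved, actions = resolve_separation(d, out)
        assert actions == []
        assert resolved.column_labels == d.column_labels

    def test_fully_separated_class_merges_to_one_or_drops(self, scheme):
        rows = [(f"p{k}", day, "carbapenems")
                for k, day in enumerate([-5, 3, 10, 17, 25])]
        d = design_with(rows, [f"p{k}" for k in range(5)] + ["x"], scheme)
        out = make_outcomes([(f"p{k}", 40 + k, "agvhd") for k in range(5)]
                            + [("x", 180, "censored")])
        resolved, actions = resolve_separation(d, out)
        carb_cols = [c for c in resolved.columns
                     if c.abx_class == "carbapenems"]
        assert len(carb_cols) <= 1
        assert detect_perfect_separation(resolved, out) == []


class TestBackwardElimination:
    def test_null_class_removed_and_aic_decreases(self):
        cfg = SimConfig(classes=("carbapenems", "fluoroquinolones"),
                        n_patients=250, seed=42)
        _cov, exposures, outcomes, _c, _ = simulate_cohort(cfg)
        design = encode_exposures(exposures, cfg.scheme, cfg.classes,
                                  patients=sorted(outcomes.patient_id))
        design, _ = resolve_separation(design, outcomes)
        fit, trace, cols = backward_eliminate(design, outcomes, None)
        assert len(trace.accepted_steps) >= 1
        aics = [trace.initial_fit.aic] + [s.aic_after
                                          for s in trace.accepted_steps]
        assert all(b < a for a, b in zip(aics, aics[1:]))
        assert fit.aic <= trace.initial_fit.aic

    def test_shared_effect_intervals_get_merged(self):
        # mutually exclusive exposure in interval 1 or 2, one shared HR of 3:
        # the merged single-coefficient model is the truth, so the merge
        # step should win on AIC
        rng = np.random.default_rng(17)
        scheme = build_interval_scheme(-7, 30, 5)
        rows, outs = [], []
        for i in range(400):
            p = f"p{i}"
            group = i % 4                     # 0: week 1, 1: week 2, 2-3: none
            expose_day = {0: 3, 1: 10}.get(group)
            if expose_day is not None:
                rows.append((p, expose_day, "carbapenems"))
            day, event = None, False
            for d in range(0, 181):
                active = expose_day is not None and d >= expose_day
                h = (0.004 if d < 90 else 0.0005) * (3.0 if active else 1.0)
                if rng.random() < 1 - np.exp(-h):
                    day, event = d, True
                    break
            outs.append((p, day if event else 180,
                         "agvhd" if event else "censored"))
        design = encode_exposures(make_records(rows), scheme,
                                  ("carbapenems",),
                                  patients=[f"p{i}" for i in range(400)])
        outcomes = make_outcomes(outs)
        design, _ = resolve_separation(design, outcomes)
        fit, trace, cols = backward_eliminate(design, outcomes, None)
        merged = [s for s in trace.accepted_steps
                  if s.action == "merge_intervals"
                  and s.abx_class == "carbapenems"
                  and {1, 2} <= set(s.interval_indices)]
        assert merged, "intervals 1-2 with a shared effect should merge"

    def test_fixed_point_when_no_candidate_improves(self):
        # single strongly significant one-interval class: nothing to merge,
        # removal not allowed, so the trace has no accepted steps
        scheme = build_interval_scheme(0, 6, 1)
        rng = np.random.default_rng(1)
        patients = [f"p{i}" for i in range(120)]
        rows, outs = [], []
        for i, p in enumerate(patients):
            exposed = i < 60
            if exposed:
                rows.append((p, 1, "carbapenems"))
            hazard = 0.05 * (4.0 if exposed else 1.0)
            day = 1 + rng.geometric(1 - np.exp(-hazard))
            if day <= 120:
                outs.append((p, int(day), "agvhd"))
            else:
                outs.append((p, 180, "censored"))
        design = encode_exposures(make_records(rows), scheme,
                                  ("carbapenems",), patients=patients)
        outcomes = make_outcomes(outs)
        fit, trace, cols = backward_eliminate(design, outcomes, None)
        assert trace.accepted_steps == []
        assert fit.aic == trace.initial_fit.aic
        assert [c.label for c in cols] == ["carbapenems__0"]

    def test_accepted_step_requires_aic_drop(self):
        with pytest.raises(InvalidArgumentError):
            SelectionStep("remove_class", "carbapenems", (0,),
                          aic_before=100.0, aic_after=100.0, accepted=True)
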