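# abxgvhd

Antibiotic exposure and acute graft-vs-host disease (aGVHD) after
allogeneic hematopoietic cell transplantation (allo-HCT): three
complementary estimators of the association between interval-coded,
time-dependent antibiotic exposures and the aGVHD hazard under competing
risk of death, exercised end-to-end on synthetic cohorts with known ground
truth.

Antibiotics perturb the gut microbiota during the peri-transplant period,
and microbiota injury is a suspected driver of aGVHD. Quantifying the
association is methodologically awkward: exposures are time-dependent and
confounded by illness (sicker patients get more antibiotics *and* more
aGVHD), and death without aGVHD competes with the event. This package is
for biostatisticians and transplant epidemiologists who want the full
modelling chain as tested, reusable code.

## The three models

Exposures are coded as one binary time-dependent covariate per (antibiotic
class × exposure interval): 17 classes × 5 intervals (pre-HCT `[-7,-1]`,
then post-HCT weeks through day 30) give 85 exposure columns; 9
nonantibiotic covariate terms complete a 94-variable design.

1. **Time-dependent competing-risk hazard model.** Weighted Cox partial
   likelihood over a counting-process expansion, with death without aGVHD
   handled Fine–Gray style: competing-event patients stay in later risk
   sets weighted by `G(t-)/G(s-)`, the Kaplan–Meier censoring survival
   ratio. Model reduction merges adjacent-interval exposures with similar
   associations or removes classes with no association, greedily accepting
   the step with the largest AIC decrease. Perfect separation on event
   occurrence is resolved by merging adjacent intervals before fitting;
   VIF diagnostics flag collinearity.
2. **Marginal structural model.** Pooled logistic treatment models per
   class (probability of initiating on a day given previous-day exposures,
   baseline covariates and measured time-varying confounders) feed
   stabilized inverse-probability-of-treatment weights
   `sw(t) = prod_{s<=t} p_num(a_s)/p_den(a_s)`; the weighted competing-risk
   fit with patient-clustered sandwich errors estimates exposure effects
   free of measured time-varying confounding.
3. **Shadow-feature (Boruta) selection.** For the binary day-180 endpoint
   (deaths without aGVHD excluded), every feature gains a shuffled shadow
   copy, a random forest scores columns by out-of-bag mean decrease
   accuracy, features beating the shadow maximum earn hits, and binomial
   tests (Bonferroni-corrected) finalize features as important or
   unimportant; runs are resumable to settle tentative features.

A seeded synthetic cohort generator (`abxgvhd.simulate`) produces
allo-HCT-like cohorts with exactly the structure these models assume —
confounded daily treatment, interval-specific multiplicative effects,
competing death, engraftment times — and records the truth used, enabling
the parameter-recovery and confounding-correction experiments in
`abxgvhd.experiments`.

## Worked example

Simulate the recovery scenario (one true hazard ratio of 2.75 on
carbapenems in the first post-transplant week, n = 2023) and fit Model 1:

```python
from abxgvhd import (preset_scenarios, simulate_cohort, encode_exposures,
                     expand_counting_process, fit_td_hazard)
from abxgvhd.pipeline import render_hr_table

cfg = preset_scenarios(seed=7)["carbapenem_week1"]
cov, abx, outcomes, conf, truth = simulate_cohort(cfg)
design = encode_exposures(abx, cfg.scheme, cfg.classes,
                          patients=sorted(outcomes["patient_id"]))
rows = expand_counting_process(design, None, outcomes, fine_gray=True)
fit = fit_td_hazard(rows, design.column_labels)
print(render_hr_table(fit).round(3))
```

The carbapenem block of the table prints:

```
          term    hr  ci_low  ci_high     p  significant
carbapenems__0 0.926   0.818    1.047 0.220        False
carbapenems__1 3.007   2.669    3.388 0.000         True
carbapenems__2 0.945   0.840    1.064 0.352        False
carbapenems__3 1.018   0.902    1.150 0.771        False
carbapenems__4 1.127   0.974    1.304 0.109        False
```

Only the week-1 term (interval index 1) is flagged, with an estimated HR of
3.01 against a generating value of 2.75 — a single replicate; across 100
replicates the mean estimate is within Monte-Carlo error of the truth (see
below). Columns `__0` … `__4` are the pre-HCT interval and post-HCT weeks
1–4.

The numbered scripts under `analysis/` walk the full study: cohort
simulation, design encoding, Model 1 with AIC selection, the MSM
bias-correction demonstration, Boruta, and the Monte-Carlo experiments;
each writes its tables under `results/`. The `abxgvhd` command-line tool
exposes the same steps (`simulate`, `encode`, `fit-cox`, `fit-msm`,
`select`, `boruta`, `run-all`, `report`).

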