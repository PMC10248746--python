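# Methods

This package implements three complementary estimators of the association
between time-dependent antibiotic exposures and acute graft-vs-host disease
(aGVHD) after allogeneic hematopoietic cell transplantation (allo-HCT),
together with a synthetic cohort generator that emulates the statistical
structure those estimators assume. This note records the models, the
numerical choices, and the places where a design decision was genuinely
open.

## Exposure design

Antibiotic administrations are person-day records (patient, integer day
relative to transplant, class). The exposure window runs from 7 days before
to 30 days after transplant and is partitioned into 5 contiguous intervals:
equal-length intervals of `floor(window/5)` days with the final interval
absorbing the remainder, which with the defaults gives pre-HCT `[-7,-1]`
and post-HCT weeks `[0,6]`, `[7,13]`, `[14,20]`, `[21,30]`. The default
catalogue holds 17 classes (cephalosporins of generation >= 3 and
penicillins each split by beta-lactamase inhibitor, vancomycin split by
route), so the full design carries 17 x 5 = 85 binary time-dependent
columns. Exposure on different days of the same interval is treated as the
same covariate value.

Two codings are implemented because the choice is not forced by the model:

* **persistent** (default): a class-interval column switches on at the
  first administration of that class in that interval and stays on, so each
  column's coefficient is the log hazard ratio from first in-interval
  exposure onward. Note that under this coding effects of the same class in
  successive intervals *add* on the log scale for a patient exposed in both.
* **transient**: the column is active only from first in-interval
  administration through the end of its interval span.

Duplicate administrations on one day collapse to a single record;
out-of-window records are dropped with a logged count.

## Model 1 — competing-risk proportional hazards

The primary event is aGVHD (grade band supplied as a label, never
computed); death without aGVHD is a competing event; follow-up is
administratively censored at day 180 (configurable). Estimation maximizes
the weighted Cox partial likelihood over a counting-process expansion: each
patient's follow-up is split at every covariate switch day into rows
`[start, stop]` (inclusive integer days; the risk set at event day t is
`start <= t <= stop`).

Competing risks are handled in the Fine–Gray (subdistribution) style:
patients with a competing event at day `s` remain in later risk sets on
each subsequent primary-event day `t`, down-weighted by
`G(t-1)/G(s-1)` where `G` is the Kaplan–Meier estimate of the censoring
survival function (a patient observed on day `d` requires `C >= d`). Their
covariate paths are carried forward from the day of the competing event
(last observation carried forward) — a modelling convention, since exposure
records end at death. With no competing events every weight is 1 and the
fit coincides with the cause-specific Cox fit exactly (asserted to 1e-8 in
the tests).

Numerics: damped Newton–Raphson with step-halving (up to 10 halvings),
convergence when the coefficient change or score max-norm falls below
1e-8, at most 100 iterations. Ties use the Efron approximation by default
(Breslow behind a flag); with case weights the Efron denominators use the
mean death weight per tied set, matching `survival::coxph` in R (our
coefficients, log-likelihoods and model-based standard errors agree with it
to machine/print precision on fixtures, weighted and unweighted, both tie
methods). Constant (degenerate) columns are dropped with a warning before
fitting. A coefficient escaping ±15 raises a separation diagnostic naming
the term. Robust (sandwich) standard errors clustered by patient are
available for weighted fits; the score residuals use the Breslow form even
under Efron estimation, a standard approximation that slightly understates
the robust variance under very heavy ties (model-based SEs are exact).

Nonantibiotic covariates: graft source (3 levels), conditioning intensity,
ATG use, donor type, GVHD prophylaxis, a donor-type x prophylaxis
interaction, and two engraftment terms — a non-engraftment indicator plus
days-to-engraftment with non-engrafters assigned the median day among
engrafters, so the indicator compares a non-engrafter with a hypothetical
median engrafter. Dummy coding against declared reference levels yields 9
model variables, for 94 in total with the 85 exposure columns.

Collinearity diagnostics: VIF_j = 1/(1 - R^2_j) from an OLS regression of
each term on the others (plus intercept) over the person-interval rows;
exact collinearity reports an infinite VIF.

## Model-reduction procedure

Before fitting, columns with perfect separation on event occurrence (all or
none of the exposed patients developed aGVHD, with at least one exposed)
are merged with an adjacent same-class interval; the earlier neighbour is
tried first, and when both neighbours exist and a fitter is supplied the
merge with the lower refit AIC wins. A fully merged class still separated
is dropped with a warning.

Backward elimination then iterates two candidate moves: (a) merge an
adjacent same-class interval pair whose terms have *similar associations* —
operationalized as both significant (two-sided Wald p < 0.05) with the same
coefficient sign, or both non-significant; (b) remove a class
non-significant in all its intervals. All candidates are refit; the one
with the lowest AIC is accepted if strictly below the current AIC, ties
going to the earliest candidate in catalogue/chronological order; selection
stops at the first iteration with no improving candidate. Whether the
original procedure chose steps greedily by AIC or in a fixed order is not
determinable, so the greedy rule is recorded explicitly in the selection
trace, which logs every evaluated and accepted step. Accepted-step AIC is
strictly decreasing by construction and verified empirically. Under
persistent coding a merged column's path equals the element-wise OR of its
members, so candidate fits reuse a single master expansion; transient
designs are re-expanded per candidate.

The severe-grade (III–IV) workflow is a configuration-driven term filter
that restricts the antibiotic terms to those significant in a previous
(grade II–IV) final model.

## Model 2 — marginal structural model

The treatment process is modelled per class as a pooled logistic regression
over eligible person-days: a class is eligible on a day if not yet
initiated in the current interval; after initiation the indicator is
deterministic within the interval and contributes probability 1. A separate
model per calendar day is unfittable at realistic sample sizes, so pooling
with interval fixed effects preserves the assumed dependence structure
(previous-day exposures plus baseline covariates) while remaining
estimable. The denominator model conditions on the previous-day exposure
vector, interval fixed effects, baseline covariates, and any measured
time-varying confounder; the numerator on the previous-day vector and
interval effects only — baseline covariates are excluded from the numerator
so the baseline terms of the outcome model absorb them. Models are fitted
by maximum likelihood (statsmodels logistic regression); perfect separation
raises an error naming the class and predictor, and any fitted probability
of exactly 0 or 1 on an observed person-day raises a positivity error.

The stabilized weight at day t is the cumulative product over decision days
s <= t and eligible classes of `p_num(a_s)/p_den(a_s)` evaluated at the
observed action (initiate or not). Weights are constant after the exposure
window closes. Identity: numerator specification equal to the denominator
forces every weight to exactly 1 and the weighted fit to reproduce the
unweighted fit bit-for-bit (same expansion, weight multiplication by 1.0).
Optional truncation at configurable percentiles is off by default. The
outcome fit multiplies stabilized weights by the Fine–Gray IPCW per row
(rows are split wherever the weight changes within a row) and reports
patient-clustered sandwich standard errors.

## Model 3 — shadow-feature (Boruta) selection

The outcome here is binary: aGVHD by day 180. Because the wrapper is not
suitable for time-to-event or competing-risk data, patients who died
without aGVHD before day 180 are excluded; patients censored before the
horizon are kept with outcome 0. Features are the 85 binary exposure
indicators (exposed in interval at all) plus the encoded covariates.

Each iteration: (1) every feature gains a freshly shuffled shadow copy;
(2) a random forest is trained on the combined matrix and each column's
importance is computed as mean decrease accuracy — for each tree, the drop
in out-of-bag accuracy when the column is permuted within the OOB sample,
averaged over trees (implemented directly on the forest's bootstrap
indices); (3) features beating the maximum shadow importance earn a hit.
After every iteration a two-sided binomial test of the hit count against
p = 0.5, Bonferroni-corrected across still-undecided features at alpha
0.05, finalizes features as important or unimportant; survivors stay
tentative and can be resolved by extending the run on the same random
stream (`run(n)` then `extend(m)` is identical to `run(n+m)`). Forest
defaults: 500 trees, `sqrt(p)` features per split, unlimited depth — the
canonical choices, since none are dictated by the procedure itself.

Two properties of the wrapper are worth flagging. First, false-selection
control is a large-sample property: a chance feature–outcome correlation
(~1/sqrt(n)) is a property of the realized dataset and persists across
iterations while shadows are re-shuffled, so at small n a lucky noise
feature can be consistently selected. Second, when applied to a binarized
survival outcome the wrapper happily selects immortal-time artifacts: a
patient must survive event-free into week 4 to be exposed in week 4, so
late-interval exposures associate with the outcome without any causal
effect (visible in the demonstration analysis on the multi-effect
scenario). Neither issue is specific to this implementation.

## Synthetic cohort generator

A discrete-time simulation on integer days (probability `1 - exp(-h)` per
day from cause-specific hazards) — simple, auditable, and matched to the
day-granular exposure data:

* baseline covariates from declared level frequencies; engraftment day
  lognormal (median 17 days, log-sd 0.20, clipped to [5, 60]) with 2%
  never engrafting;
* daily treatment process per class: logistic initiation with intercept
  −3.2 (~4% per eligible day), previous-day same-class effect +1.5
  (treatment persistence), optional baseline-covariate and confounder
  effects — exactly the dependence structure the MSM assumes;
* a peri-transplant illness confounder: a Markov daily indicator that
  evolves during the exposure window and is carried forward afterwards; in
  the confounded scenarios it is absorbing (p_on 0.015/day, p_stay 1.0)
  with logit +1.5 on initiation and +1.5 on the log aGVHD hazard;
* cause-specific aGVHD hazard: piecewise-constant weekly baseline
  (0.007, 0.011, 0.020, 0.024, 0.022, 0.017, 0.011, 0.007, then 0.003/day),
  multiplied by `exp(beta)` for each active class-interval exposure under
  persistent coding, times any confounder effect; constant competing death
  hazard (default 6e-4/day); administrative censoring at day 180 and no
  other loss to follow-up, as in a registry cohort with complete follow-up.

Under the effect-free defaults the day-180 aGVHD incidence falls in the
60–80% band with onset median around four weeks, emulating a
high-incidence transplant center; these are realism checks on the
generator, never validation targets for real data. Within a day the order
is confounder update, treatment decisions, event sampling, so a same-day
exposure already acts on that day's hazard — matching the encoding, where
a column is on from its first administration day.

Preset scenarios (ground truth recorded alongside every cohort): `null`
(no effects, full catalogue), `confounded_null` (illness drives both
initiation and hazard, every true HR = 1), `carbapenem_week1` (one true
HR of 2.75 on carbapenems in week 1), `multi_effect` (three nonzero HRs
with measured confounding). The recovery scenario sets the competing death
hazard to zero: the generator defines effects on the cause-specific
hazard, and with competing deaths present the subdistribution HR estimated
by the Fine–Gray fit is attenuated relative to the generating
cause-specific HR — an estimand difference, not an estimation error — so
the generating value is an exact truth for the fitted model only when the
two coincide. Competing death remains active in the other scenarios and in
the IPCW unit fixtures. The demonstration scenarios use a 3–4 class
catalogue so the treatment models and weights stay well-conditioned at the
cohort sizes simulated.

## Problem sizes in tests and the reproduction script

Monte-Carlo checks run at sizes chosen for a single CPU: recovery uses 100
replicates at the full cohort size (n = 2023), the confounding comparison
10 batches of 3 replicates at n = 500, null-data selection 50 replicates at
n = 150 with 3 classes, and the Boruta null control 5 seeds at n = 500 —
the sample size at which false-selection control is expected to hold (see
above). Tolerances are Monte-Carlo-aware: the recovery check requires the
mean estimate within 2 Monte-Carlo standard errors of log 2.75 and CI
coverage within [0.91, 0.99].

## Known limitations

* Exposure is binary per class-interval: no dose, route (beyond the
  vancomycin split), or duration weighting.
* The generator's co-prescription structure is first-order only
  (previous-day dependence); real antibiotic courses are longer-range, and
  microbiome dynamics are out of scope entirely.
* Fine–Gray with time-dependent covariates requires a convention for
  covariate paths after the competing event; LOCF is used and documented,
  but other conventions exist.
* The robust-variance Breslow approximation under heavy ties, and the
  pooled (rather than per-day) treatment models, are deliberate
  approximations noted above; per-day treatment fitting is available
  behind a flag but needs far larger cohorts.
* Passing tests on synthetic cohorts show the estimators recover the
  structure this generator encodes; they cannot certify behaviour under
  real-world features the generator omits (informative censoring,
  unmeasured confounding beyond the illness toggle, measurement error).
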