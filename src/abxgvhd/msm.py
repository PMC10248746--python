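"""Marginal structural model machinery: treatment models and stabilized IPTW.

The treatment process assumed by the MSM: the vector of antibiotic exposures
on a given day depends on the previous day's exposures and on baseline
covariates (plus, optionally, a measured time-varying confounder).  Each
class's initiation is modelled by pooled logistic regression over eligible
person-days with interval fixed effects; a class is "eligible" on a day if
it has not yet been initiated in the current interval (after initiation the
indicator is deterministic and contributes probability 1).

Stabilized weight at day t:  sw(t) = prod over s <= t, classes eligible at s
of p_num(a_s) / p_den(a_s), where a_s is the action actually observed
(initiate vs not).  The numerator model conditions on treatment history and
interval only; the denominator adds baseline covariates and confounders, so
under no confounding the two coincide and every weight is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposure import ExposureDesign, InvalidArgumentError
from .survival import FitResult, fit_td_hazard

logger = logging.getLogger(__name__)


class PositivityError(RuntimeError):
    """A treatment probability of exactly 0 or 1 on an observed person-day."""


class TreatmentSeparationError(RuntimeError):
    def __init__(self, abx_class, predictor):
        self.abx_class = abx_class
        self.predictor = predictor
        super().__init__(
            f"perfect separation fitting treatment model for {abx_class!r} "
            f"(predictor {predictor!r})")


@dataclass
class TreatmentModel:
    """Fitted pooled logistic model for daily initiation of one class."""

    abx_class: str
    kind: str                 # "numerator" | "denominator"
    predictors: list[str]     # columns actually used (constants dropped)
    params: np.ndarray

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(frame))]
                            + [frame[c].to_numpy(float) for c in self.predictors])
        eta = X @ self.params
        return 1.0 / (1.0 + np.exp(-eta))


def _prev_active_frame(design: ExposureDesign, days: np.ndarray,
                       patients) -> dict[str, pd.DataFrame]:
    """Per class: (patients x days) indicator of any administration <= day-1."""
    out = {}
    for cls in design.catalogue:
        cols = [c.label for c in design.columns if c.abx_class == cls]
        first = design.first_day.loc[patients, cols].min(axis=1).to_numpy()
        out[cls] = (days[None, :] - 1 >= first[:, None]).astype(float)
    return out


def build_person_day_table(design: ExposureDesign,
                           outcomes: pd.DataFrame,
                           covariates: pd.DataFrame | None = None,
                           confounder_paths: pd.DataFrame | None = None,
                           horizon: int = 180) -> pd.DataFrame:
    """Eligible treatment-decision rows, one per (patient, day, class).

    Columns: identifiers, ``initiate`` (observed action), ``interval``,
    ``prev__<class>`` history indicators, baseline covariate columns, and
    ``confounder`` if paths were supplied (long frame with
    ``patient_id, day, value``).
    """
    scheme = design.scheme
    out_map = outcomes.set_index("patient_id")["event_day"].to_dict()
    days = np.arange(scheme.window_start, scheme.window_end + 1)
    intervals = np.array([scheme.interval_of(int(d)) for d in days])
    patients = design.patients
    prev = _prev_active_frame(design, days, patients)

    conf_lookup = None
    if confounder_paths is not None:
        conf_lookup = confounder_paths.set_index(["patient_id", "day"])["value"]

    recs = []
    for i, pid in enumerate(patients):
        stop = min(int(out_map[pid]), horizon)
        for j, d in enumerate(days):
            if d > stop:
                break
            k = intervals[j]
            for cls in design.catalogue:
                lab = f"{cls}__{k}"
                fd = design.first_day.at[pid, lab] if lab in design.first_day else np.nan
                if not np.isnan(fd) and fd < d:
                    continue  # already initiated in this interval
                initiate = 1 if (not np.isnan(fd) and fd == d) else 0
                row = {"patient_id": pid, "day": int(d), "abx_class": cls,
                       "interval": int(k), "initiate": initiate}
                for c2 in design.catalogue:
                    row[f"prev__{c2}"] = prev[c2][i, j]
                if conf_lookup is not None:
                    row["confounder"] = float(conf_lookup.get((pid, int(d)), 0.0))
                recs.append(row)
    table = pd.DataFrame.from_records(recs)
    if covariates is not None and len(table):
        table = table.merge(covariates.reset_index().rename(
            columns={covariates.index.name or "index": "patient_id"}),
            on="patient_id", how="left")
    return table


def _fit_pooled_logit(frame: pd.DataFrame, abx_class: str, kind: str,
                      predictors: list[str]) -> TreatmentModel:
    y = frame["initiate"].to_numpy(float)
    kept = [c for c in predictors
            if frame[c].nunique() > 1]
    X = sm.add_constant(frame[kept].to_numpy(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
    except Exception as exc:  # statsmodels separation/convergence failures
        raise TreatmentSeparationError(abx_class, "unknown") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or (
            len(params) > 1 and np.max(np.abs(params[1:])) > 25):
        j = int(np.argmax(np.abs(params[1:]))) if len(params) > 1 else 0
        raise TreatmentSeparationError(abx_class, kept[j] if kept else "intercept")
    model = TreatmentModel(abx_class, kind, kept, params)
    p = model.predict_proba(frame)
    if np.any(p <= 0) or np.any(p >= 1):
        raise TreatmentSeparationError(abx_class, "fitted probabilities at 0/1")
    return model


def fit_treatment_models(design: ExposureDesign,
                         outcomes: pd.DataFrame,
                         covariates: pd.DataFrame | None = None,
                         confounder_paths: pd.DataFrame | None = None,
                         horizon: int = 180,
                         person_days: pd.DataFrame | None = None):
    """Numerator and denominator treatment models for every class.

    Returns ``(models, person_days)`` where models maps class ->
    ``(numerator, denominator)`` (``None`` for classes never initiated, which
    contribute weight 1).  The denominator conditions on previous-day
    exposures, interval fixed effects, baseline covariates and any supplied
    confounder; the numerator on previous-day exposures and interval effects
    only, so with no covariates and no confounder the two specifications
    coincide.
    """
    if person_days is None:
        person_days = build_person_day_table(design, outcomes, covariates,
                                             confounder_paths, horizon)
    n_int = design.scheme.n_intervals
    interval_dummies = []
    for k in range(1, n_int):
        person_days[f"interval__{k}"] = (person_days["interval"] == k).astype(float)
        interval_dummies.append(f"interval__{k}")
    prev_cols = [f"prev__{c}" for c in design.catalogue]
    base_cols = list(covariates.columns) if covariates is not None else []
    conf_cols = ["confounder"] if confounder_paths is not None else []

    models = {}
    for cls in design.catalogue:
        sub = person_days[person_days["abx_class"] == cls]
        if sub.empty or sub["initiate"].sum() == 0:
            logger.warning("class %r never initiated: treatment model skipped "
                           "(weight contribution 1)", cls)
            models[cls] = None
            continue
        num = _fit_pooled_logit(sub, cls, "numerator",
                                prev_cols + interval_dummies)
        den = _fit_pooled_logit(sub, cls, "denominator",
                                prev_cols + interval_dummies + base_cols
                                + conf_cols)
        models[cls] = (num, den)
    return models, person_days


@dataclass
class WeightSeries:
    """Per-person-day stabilized weights with exact summary diagnostics."""

    frame: pd.DataFrame          # index patients, columns = window days, sw(t)
    window_start: int
    window_end: int

    def weight_at(self, patient, day: int) -> float:
        d = min(max(int(day), self.window_start), self.window_end)
        return float(self.frame.at[patient, d])

    def diagnostics(self) -> dict:
        vals = self.frame.to_numpy(float).ravel()
        qs = np.percentile(vals, [1, 5, 25, 50, 75, 95, 99])
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "min": float(vals.min()), "max": float(vals.max()),
                "percentiles": {str(q): float(v)
                                for q, v in zip([1, 5, 25, 50, 75, 95, 99], qs)}}

    def truncate(self, lower_pct: float, upper_pct: float) -> "WeightSeries":
        vals = self.frame.to_numpy(float)
        lo, hi = np.percentile(vals.ravel(), [lower_pct, upper_pct])
        return WeightSeries(pd.DataFrame(np.clip(vals, lo, hi),
                                         index=self.frame.index,
                                         columns=self.frame.columns),
                            self.window_start, self.window_end)

    def to_person_day_csv(self, path) -> None:
        long = self.frame.stack().rename("stabilized_weight").reset_index()
        long.columns = ["patient_id", "day", "stabilized_weight"]
        long.to_csv(path, index=False)


def cumulative_stabilized_weight(p_num, p_den) -> float:
    """Product of per-decision numerator/denominator observed-action probabilities."""
    p_num = np.asarray(p_num, dtype=float)
    p_den = np.asarray(p_den, dtype=float)
    if np.any((p_den <= 0) | (p_den >= 1)):
        raise PositivityError("denominator probability at 0 or 1")
    return float(np.prod(p_num / p_den))


def stabilized_weights(models, design: ExposureDesign,
                       person_days: pd.DataFrame) -> WeightSeries:
    """Cumulative stabilized IPTW per patient per window day.

    For each eligible person-day decision, the observed action (initiate or
    not) contributes p_num/p_den evaluated at that action; classes already
    switched on in the current interval contribute 1; days after the window
    keep the last window weight.  Deterministic given the fitted models.
    """
    scheme = design.scheme
    days = np.arange(scheme.window_start, scheme.window_end + 1)
    patients = design.patients
    ratio = np.ones((len(patients), len(days)))
    pidx = {p: i for i, p in enumerate(patients)}
    didx = {int(d): j for j, d in enumerate(days)}

    for cls in design.catalogue:
        pair = models.get(cls)
        if pair is None:
            continue
        num, den = pair
        sub = person_days[person_days["abx_class"] == cls]
        if sub.empty:
            continue
        p_num = num.predict_proba(sub)
        p_den = den.predict_proba(sub)
        if np.any((p_den <= 0.0) | (p_den >= 1.0)):
            raise PositivityError(
                f"positivity violation for {cls!r}: denominator probability "
                "of 0 or 1 on an observed person-day")
        act = sub["initiate"].to_numpy(float)
        obs_num = np.where(act == 1, p_num, 1.0 - p_num)
        obs_den = np.where(act == 1, p_den, 1.0 - p_den)
        rows = [pidx[p] for p in sub["patient_id"]]
        cols = [didx[int(d)] for d in sub["day"]]
        np.multiply.at(ratio, (rows, cols), obs_num / obs_den)

    sw = np.cumprod(ratio, axis=1)
    frame = pd.DataFrame(sw, index=patients, columns=[int(d) for d in days])
    return WeightSeries(frame, scheme.window_start, scheme.window_end)


def _split_rows_at_weight_changes(expansion: pd.DataFrame,
                                  ws: WeightSeries) -> pd.DataFrame:
    """Split rows so the stabilized weight is constant within each row."""
    sw = ws.frame
    out_rows = []
    changed = False
    for rec in expansion.to_dict("records"):
        pid, a, b = rec["patient_id"], int(rec["start"]), int(rec["stop"])
        lo = max(a + 1, ws.window_start + 1)
        hi = min(b, ws.window_end)
        cuts = [d for d in range(lo, hi + 1)
                if sw.at[pid, d] != sw.at[pid, d - 1]]
        if not cuts:
            out_rows.append(rec)
            continue
        changed = True
        bounds = [a] + cuts + [b + 1]
        for x, y in zip(bounds, bounds[1:]):
            r = dict(rec)
            r["start"], r["stop"] = x, y - 1
            r["event"] = rec["event"] if y - 1 == b else 0
            out_rows.append(r)
    if not changed:
        return expansion
    return pd.DataFrame(out_rows, columns=expansion.columns)


def fit_msm(expansion: pd.DataFrame, weight_series: WeightSeries | None,
            terms: list[str], ties: str = "efron",
            robust: bool = True) -> FitResult:
    """Weighted competing-risk fit: row weight = stabilized IPTW x IPCW.

    With a trivial (all-one) weight series the expansion passes through
    unchanged and the fit reproduces the unweighted fit exactly.  Robust
    sandwich standard errors are clustered by patient.
    """
    if weight_series is not None:
        expansion = _split_rows_at_weight_changes(expansion, weight_series)
        w = np.array([weight_series.weight_at(p, int(t))
                      for p, t in zip(expansion["patient_id"],
                                      expansion["stop"])])
    else:
        w = None
    return fit_td_hazard(expansion, terms, weights=w, ties=ties,
                         robust_cluster="patient_id" if robust else None)
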