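"""Proportional-hazards engine for time-dependent covariates with competing risks.

The primary event is acute GVHD; death without GVHD is a competing event.
Competing risks are handled in the Fine-Gray (subdistribution hazard) style:
patients with a competing event remain in later risk sets, down-weighted by
the Kaplan-Meier estimate of the censoring distribution (inverse probability
of censoring weighting, IPCW).  Follow-up is in integer days; a row
(start, stop] of the counting-process expansion covers event days
``start <= t <= stop`` inclusively.

Estimation maximizes the weighted partial likelihood (Efron or Breslow tie
handling) by damped Newton-Raphson.  Robust (sandwich) standard errors
clustered by patient are available for weighted fits.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import ExposureDesign, InvalidArgumentError

logger = logging.getLogger(__name__)

EVENT_TYPES = ("agvhd", "death", "censored")
Z975 = stats.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Monotone partial likelihood: a coefficient diverges.

    Typically caused by perfect separation on event occurrence for a binary
    covariate; the offending term is named in the message.
    """

    def __init__(self, term):
        self.term = term
        super().__init__(f"monotone likelihood: coefficient for {term!r} diverges "
                         "(perfect separation on event occurrence?)")


# ---------------------------------------------------------------------------
# outcomes & covariates

def validate_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    req = {"patient_id", "event_day", "event_type"}
    if not req.issubset(outcomes.columns):
        raise InvalidArgumentError(f"outcomes must have columns {sorted(req)}")
    bad = set(outcomes["event_type"]) - set(EVENT_TYPES)
    if bad:
        raise InvalidArgumentError(f"unknown event types: {sorted(bad)}")
    if outcomes["patient_id"].duplicated().any():
        dup = outcomes.loc[outcomes["patient_id"].duplicated(), "patient_id"]
        raise InvalidArgumentError(f"duplicate outcome rows for {sorted(set(dup))}")
    return outcomes


def read_outcomes(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "event_type": str})
    df["event_day"] = df["event_day"].astype(int)
    return validate_outcomes(df)


#: Declared level sets for the baseline covariate table.  The reference level
#: is listed first; dummy coding against it plus the donor x prophylaxis
#: interaction and the two engraftment terms yields 9 model variables.
DEFAULT_COVARIATE_SCHEMA = {
    "graft_source": ["pbsc", "bone_marrow", "cord_blood"],
    "conditioning_intensity": ["myeloablative", "reduced_intensity"],
    "atg_use": ["no", "yes"],
    "donor_type": ["related", "unrelated"],
    "gvhd_prophylaxis": ["cni_based", "ptcy_based"],
}


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return df.set_index("patient_id")


def engraftment_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Two engraftment model terms per patient.

    Engrafters get indicator 0 and their observed day; non-engrafters get
    indicator 1 and the median engraftment day among engrafters, so the
    indicator coefficient compares a non-engrafter with a hypothetical
    patient engrafting at the median.
    """
    engrafted = cov["engrafted"].astype(bool)
    if not engrafted.any():
        raise InvalidArgumentError(
            "no engrafted patients: median engraftment day undefined")
    days = pd.to_numeric(cov["engraftment_day"], errors="coerce")
    med = float(days[engrafted].median())
    out = pd.DataFrame(index=cov.index)
    out["non_engrafted"] = (~engrafted).astype(float)
    out["days_to_engraftment"] = np.where(engrafted, days, med)
    return out


def covariate_model_matrix(cov: pd.DataFrame,
                           schema=DEFAULT_COVARIATE_SCHEMA) -> pd.DataFrame:
    """Numeric design for the nonantibiotic covariates (9 columns by default).

    Categoricals are dummy-coded against the first declared level, a
    donor-type x GVHD-prophylaxis interaction term is added, and the two
    engraftment terms are appended.
    """
    out = pd.DataFrame(index=cov.index)
    for name, levels in schema.items():
        observed = set(cov[name].astype(str))
        bad = observed - set(levels)
        if bad:
            raise InvalidArgumentError(
                f"covariate {name!r} has undeclared levels {sorted(bad)}")
        for lev in levels[1:]:
            out[f"{name}__{lev}"] = (cov[name].astype(str) == lev).astype(float)
    if "donor_type" in schema and "gvhd_prophylaxis" in schema:
        d = (cov["donor_type"].astype(str) != schema["donor_type"][0]).astype(float)
        p = (cov["gvhd_prophylaxis"].astype(str)
             != schema["gvhd_prophylaxis"][0]).astype(float)
        out["donor_x_prophylaxis"] = d * p
    eng = engraftment_covariates(cov)
    out["non_engrafted"] = eng["non_engrafted"]
    out["days_to_engraftment"] = eng["days_to_engraftment"]
    return out


# ---------------------------------------------------------------------------
# censoring distribution & Fine-Gray IPCW

def censoring_survival(outcomes: pd.DataFrame, horizon: int = 180):
    """Kaplan-Meier estimate of the censoring distribution G(d) = P(C > d).

    Censoring (including administrative censoring at the horizon) is the
    "event"; GVHD and death act as censoring of the censoring time.  Returns
    ``(days, G)`` where G[i] applies to all d in [days[i], days[i+1]).
    """
    validate_outcomes(outcomes)
    obs = np.minimum(outcomes["event_day"].to_numpy(), horizon)
    is_cens = ((outcomes["event_type"] == "censored")
               | (outcomes["event_day"] > horizon)).to_numpy()
    order = np.argsort(obs)
    obs, is_cens = obs[order], is_cens[order]
    cens_days = np.unique(obs[is_cens])
    n = len(obs)
    G_days = [-np.inf]
    G_vals = [1.0]
    g = 1.0
    for d in cens_days:
        at_risk = np.sum(obs >= d)
        d_c = np.sum((obs == d) & is_cens)
        g *= 1.0 - d_c / at_risk
        G_days.append(d)
        G_vals.append(g)
    days_arr = np.array(G_days, dtype=float)

    def G(day):
        """P(C > day) as a right-continuous step function."""
        i = np.searchsorted(days_arr, day, side="right") - 1
        return np.asarray(G_vals, dtype=float)[i]

    return G


def fine_gray_ipcw(outcomes: pd.DataFrame, horizon: int = 180) -> pd.DataFrame:
    """Per-person-day IPCW weights extending competing-event patients.

    A patient with a competing event at day ``s`` stays "at risk" on each
    later primary-event day ``t`` with weight G(t-1)/G(s-1), where G is the
    Kaplan-Meier censoring survival (a patient observed on day d requires
    C >= d, i.e. C > d-1).  Patients without competing events have weight 1
    while at risk.  Returns rows (patient_id, day, weight) for the extension
    days only.
    """
    validate_outcomes(outcomes)
    if outcomes.empty:
        raise InvalidArgumentError("outcomes must be non-empty")
    G = censoring_survival(outcomes, horizon)
    prim_days = np.unique(
        outcomes.loc[(outcomes["event_type"] == "agvhd")
                     & (outcomes["event_day"] <= horizon), "event_day"])
    rows = []
    comp = outcomes[(outcomes["event_type"] == "death")
                    & (outcomes["event_day"] <= horizon)]
    for pid, s in zip(comp["patient_id"], comp["event_day"]):
        g_s = float(G(s - 1))
        if g_s == 0.0:
            raise InvalidArgumentError(
                f"G(t-) = 0 at competing event of {pid!r}: IPCW weight undefined")
        for t in prim_days[(prim_days > s) & (prim_days <= horizon)]:
            rows.append((pid, int(t), float(G(t - 1)) / g_s))
    return pd.DataFrame(rows, columns=["patient_id", "day", "weight"])


# ---------------------------------------------------------------------------
# counting-process expansion

def expand_counting_process(design: ExposureDesign,
                            covariates: pd.DataFrame | None,
                            outcomes: pd.DataFrame,
                            horizon: int = 180,
                            fine_gray: bool = True,
                            entry_day: int | None = None) -> pd.DataFrame:
    """Person-interval rows (patient, start, stop, covariates, event, weight).

    Follow-up [entry, min(event_day, horizon)] is broken at every covariate
    switch day, the event flag set on the terminal row only.  With
    ``fine_gray=True``, competing-event patients are extended past their
    death on every later primary-event day as single-day rows carrying the
    IPCW weight (column ``fg_weight``), covariate paths carried forward from
    the day of the competing event.
    """
    validate_outcomes(outcomes)
    if entry_day is None:
        entry_day = design.scheme.window_start
    out_map = outcomes.set_index("patient_id")
    missing = [p for p in design.patients if p not in out_map.index]
    if missing:
        raise InvalidArgumentError(f"patients missing outcomes: {missing[:5]}")
    if covariates is not None:
        miss_cov = [p for p in design.patients if p not in covariates.index]
        if miss_cov:
            raise InvalidArgumentError(f"patients missing covariates: {miss_cov[:5]}")

    labels = design.column_labels
    cov_cols = list(covariates.columns) if covariates is not None else []
    ipcw = fine_gray_ipcw(outcomes, horizon) if fine_gray else None

    recs: list[tuple] = []
    for pid in design.patients:
        etype = out_map.at[pid, "event_type"]
        eday = int(out_map.at[pid, "event_day"])
        stop = min(eday, horizon)
        event = 1 if (etype == "agvhd" and eday <= horizon) else 0
        switches = design.switch_days(pid)
        cuts = set()
        for on, off in switches.values():
            if entry_day < on <= stop:
                cuts.add(on)
            if off is not None and entry_day < off <= stop:
                cuts.add(off)
        bounds = [entry_day] + sorted(cuts) + [stop + 1]
        base_cov = (tuple(covariates.loc[pid, cov_cols]) if cov_cols else ())

        def col_vals(day):
            vals = []
            for lab in labels:
                on_off = switches.get(lab)
                if on_off is None:
                    vals.append(0.0)
                else:
                    on, off = on_off
                    vals.append(1.0 if (day >= on and (off is None or day < off))
                                else 0.0)
            return tuple(vals)

        for a, b in zip(bounds, bounds[1:]):
            recs.append((pid, a, b - 1, 1.0,
                         event if b - 1 == stop else 0) + col_vals(a) + base_cov)

        if fine_gray and etype == "death" and eday <= horizon:
            # carried-forward covariate values from the day of death
            frozen = col_vals(stop)
            ext = ipcw[ipcw["patient_id"] == pid]
            for _, r in ext.iterrows():
                recs.append((pid, int(r["day"]), int(r["day"]),
                             float(r["weight"]), 0) + frozen + base_cov)

    frame = pd.DataFrame.from_records(
        recs, columns=["patient_id", "start", "stop", "fg_weight", "event"]
        + labels + cov_cols)
    return frame


# ---------------------------------------------------------------------------
# fit result container

@dataclass
class FitResult:
    """Coefficients, HRs with 95% CIs, and diagnostics of a hazard-model fit."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    aic: float
    n_events: int
    n_rows: int
    converged: bool
    n_iterations: int
    ties: str
    dropped_terms: list[str] = field(default_factory=list)
    robust: bool = False
    covariance: np.ndarray | None = None

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms, "coef": self.coef, "se": self.se,
            "hr": self.hazard_ratios, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p_values,
        })

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.coef.tolist(),
            "standard_errors": self.se.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "p_values": self.p_values.tolist(),
            "log_likelihood": self.log_likelihood,
            "log_likelihood_null": self.log_likelihood_null,
            "aic": self.aic,
            "n_events": self.n_events,
            "n_rows": self.n_rows,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "ties": self.ties,
            "robust": self.robust,
            "dropped_terms": list(self.dropped_terms),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# partial likelihood internals

def _risk_suffix_sums(key_counts, values, K):
    """Suffix sums of per-bucket aggregates; bucket g holds rows with key == g."""
    # values: (n, ...) ; key_counts: (n,) ints in [0, K]
    out_shape = (K + 1,) + values.shape[1:]
    agg = np.zeros(out_shape)
    np.add.at(agg, key_counts, values)
    suff = np.cumsum(agg[::-1], axis=0)[::-1]
    # suff[g] = sum over rows with key >= g ; S at event index i needs key > i
    return suff


def _loglik_parts(beta, X, w, start, stop, event, times, need_grad=True,
                  ties="efron"):
    """Weighted partial log-likelihood, gradient and information matrix."""
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    eta = np.clip(eta, -500, 500)
    r = w * np.exp(eta)
    rX = r[:, None] * X if p else np.zeros((n, 0))

    K = len(times)
    ca = np.searchsorted(times, stop, side="right")   # at risk for i < ca
    cb = np.searchsorted(times, start, side="left")   # at risk for i >= cb
    # S(t_i) = sum over rows with cb <= i < ca
    suffA0 = _risk_suffix_sums(ca, r, K)
    suffB0 = _risk_suffix_sums(cb, r, K)
    S0 = suffA0[1:] - suffB0[1:]        # (K,)
    if p:
        suffA1 = _risk_suffix_sums(ca, rX, K)
        suffB1 = _risk_suffix_sums(cb, rX, K)
        S1 = suffA1[1:] - suffB1[1:]    # (K, p)
    else:
        S1 = np.zeros((K, 0))

    S2 = None
    if need_grad and p:
        S2 = np.zeros((K, p, p))
        for key in (ca, cb):
            order = np.argsort(key, kind="stable")
            ks = key[order]
            Xo, rXo = X[order], rX[order]
            sign = 1.0 if key is ca else -1.0
            acc = np.zeros((p, p))
            # accumulate buckets from the top down: bucket g contributes to i < g
            edges = np.searchsorted(ks, np.arange(K + 2))
            for g in range(K, 0, -1):
                lo, hi = edges[g], edges[g + 1]
                if hi > lo:
                    acc += Xo[lo:hi].T @ rXo[lo:hi]
                S2[g - 1] += sign * acc

    # per-event-time death aggregates
    ev = event.astype(bool)
    Xe, we, re_, stope = X[ev], w[ev], r[ev], stop[ev]
    ki = np.searchsorted(times, stope)
    ll = float(np.sum(we * eta[ev]))
    U = np.sum(we[:, None] * Xe, axis=0) if p else np.zeros(0)
    Info = np.zeros((p, p))

    for k in range(K):
        sel = ki == k
        d = int(sel.sum())
        if d == 0:
            continue
        Wd = float(we[sel].sum())
        if ties == "breslow" or d == 1:
            fracs = [0.0]
        else:
            fracs = [l / d for l in range(d)]
        S0D = float(re_[sel].sum())
        S1D = rX[ev][sel].sum(axis=0) if p else np.zeros(0)
        if need_grad and p:
            Xs = Xe[sel]
            rs = re_[sel]
            S2D = Xs.T @ (rs[:, None] * Xs)
        wd_l = Wd / len(fracs)
        for f in fracs:
            s0 = S0[k] - f * S0D
            ll -= wd_l * np.log(s0)
            if need_grad and p:
                s1 = S1[k] - f * S1D
                xbar = s1 / s0
                U -= wd_l * xbar
                s2 = S2[k] - f * S2D
                Info += wd_l * (s2 / s0 - np.outer(xbar, xbar))
    return ll, U, Info, S0, S1


def fit_td_hazard(expansion: pd.DataFrame, terms: list[str],
                  weights: np.ndarray | None = None,
                  ties: str = "efron",
                  robust_cluster: str | None = None,
                  drop_degenerate: bool = True,
                  max_iter: int = 100, tol: float = 1e-8,
                  max_halvings: int = 10,
                  beta_bound: float = 15.0) -> FitResult:
    """Maximize the weighted partial likelihood over counting-process rows.

    ``expansion`` must carry columns ``patient_id, start, stop, event`` and
    every name in ``terms``; an ``fg_weight`` column (IPCW) multiplies any
    per-row ``weights`` supplied (e.g. stabilized IPTW).  Newton-Raphson with
    step-halving; deterministic given inputs.  Degenerate (constant) term
    columns are dropped with a warning.  A coefficient escaping
    ``[-beta_bound, beta_bound]`` raises :class:`SeparationError` naming the
    term.  ``robust_cluster`` (usually ``"patient_id"``) requests sandwich
    standard errors clustered on that column.
    """
    if ties not in ("efron", "breslow"):
        raise InvalidArgumentError(f"unknown tie handling {ties!r}")
    terms = list(terms)
    n = len(expansion)
    w = np.ones(n)
    if "fg_weight" in expansion.columns:
        w = w * expansion["fg_weight"].to_numpy(float)
    if weights is not None:
        w = w * np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise InvalidArgumentError("all row weights must be > 0")

    dropped = []
    if drop_degenerate:
        keep = []
        for t in terms:
            v = expansion[t].to_numpy(float)
            if np.all(v == v[0]):
                dropped.append(t)
                logger.warning("dropping degenerate column %r (constant over "
                               "the risk experience)", t)
            else:
                keep.append(t)
        terms = keep

    X = expansion[terms].to_numpy(float) if terms else np.zeros((n, 0))
    start = expansion["start"].to_numpy(float)
    stop = expansion["stop"].to_numpy(float)
    event = expansion["event"].to_numpy(int)
    n_events = int(event.sum())
    if n_events < 1:
        raise InvalidArgumentError("need >= 1 primary event to fit")
    times = np.unique(stop[event.astype(bool)])
    p = len(terms)

    ll_null, *_ = _loglik_parts(np.zeros(p), X, w, start, stop, event, times,
                                need_grad=False, ties=ties)

    beta = np.zeros(p)
    ll = ll_null
    converged = False
    it = 0
    Info = np.eye(max(p, 1))
    if p == 0:
        converged = True
    for it in range(1, max_iter + 1):
        if p == 0:
            break
        _, U, Info, _, _ = _loglik_parts(beta, X, w, start, stop, event, times,
                                         ties=ties)
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(Info, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Info, U, rcond=None)[0]
        new_beta = beta + step
        new_ll, *_ = _loglik_parts(new_beta, X, w, start, stop, event, times,
                                   need_grad=False, ties=ties)
        halved = 0
        while new_ll < ll - 1e-12 and halved < max_halvings:
            step = step / 2.0
            new_beta = beta + step
            new_ll, *_ = _loglik_parts(new_beta, X, w, start, stop, event,
                                       times, need_grad=False, ties=ties)
            halved += 1
        if np.max(np.abs(new_beta)) > beta_bound:
            j = int(np.argmax(np.abs(new_beta)))
            raise SeparationError(terms[j])
        delta = np.max(np.abs(new_beta - beta))
        beta, ll = new_beta, new_ll
        if delta < tol:
            converged = True
            break

    if p:
        ll, U, Info, S0, S1 = _loglik_parts(beta, X, w, start, stop, event,
                                            times, ties=ties)
        cov = np.linalg.inv(Info)
    else:
        cov = np.zeros((0, 0))

    robust = False
    if robust_cluster is not None and p:
        cov = _sandwich_cov(expansion, X, w, beta, start, stop, event, times,
                            cov, robust_cluster)
        robust = True

    se = np.sqrt(np.diag(cov)) if p else np.zeros(0)
    hr = np.exp(beta)
    ci_lo = np.exp(beta - Z975 * se)
    ci_hi = np.exp(beta + Z975 * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.norm.sf(np.abs(z))
    return FitResult(
        terms=terms, coef=beta, se=se, hazard_ratios=hr, ci_low=ci_lo,
        ci_high=ci_hi, p_values=pvals, log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        aic=-2.0 * float(ll) + 2.0 * p, n_events=n_events, n_rows=n,
        converged=converged, n_iterations=it, ties=ties,
        dropped_terms=dropped, robust=robust, covariance=cov)


def _sandwich_cov(expansion, X, w, beta, start, stop, event, times, naive_cov,
                  cluster_col):
    """Cluster-robust sandwich covariance from (Breslow-style) score residuals."""
    K = len(times)
    p = X.shape[1]
    eta = np.clip(X @ beta, -500, 500)
    r = w * np.exp(eta)
    rX = r[:, None] * X
    ca = np.searchsorted(times, stop, side="right")
    cb = np.searchsorted(times, start, side="left")
    S0 = (_risk_suffix_sums(ca, r, K) - _risk_suffix_sums(cb, r, K))[1:]
    S1 = (_risk_suffix_sums(ca, rX, K) - _risk_suffix_sums(cb, rX, K))[1:]
    ev = event.astype(bool)
    we = w[ev]
    ki = np.searchsorted(times, stop[ev])
    Wd = np.zeros(K)
    np.add.at(Wd, ki, we)
    xbar = S1 / S0[:, None]
    h = Wd / S0                                   # (K,)
    C0 = np.concatenate([[0.0], np.cumsum(h)])
    C1 = np.concatenate([np.zeros((1, p)), np.cumsum(h[:, None] * xbar, axis=0)])
    # row i at risk for event-time indices [cb_i, ca_i)
    sum0 = C0[ca] - C0[cb]
    sum1 = C1[ca] - C1[cb]
    resid = -(r[:, None] * (X * sum0[:, None] - sum1))
    resid[ev] += we[:, None] * (X[ev] - xbar[ki])
    groups = expansion[cluster_col].to_numpy()
    df = pd.DataFrame(resid)
    df["__g"] = groups
    Ug = df.groupby("__g").sum().to_numpy()
    meat = Ug.T @ Ug
    return naive_cov @ meat @ naive_cov


# ---------------------------------------------------------------------------
# collinearity diagnostics

def compute_vif(expansion: pd.DataFrame, terms: list[str]) -> pd.Series:
    """Variance inflation factors over the person-interval rows.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from an OLS regression of term
    j on all other terms plus an intercept.  Exact collinearity reports an
    infinite VIF.
    """
    terms = list(terms)
    if len(terms) < 2:
        raise InvalidArgumentError("VIF needs >= 2 terms")
    X = expansion[terms].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise InvalidArgumentError("need more rows than terms for VIF")
    out = {}
    ones = np.ones((n, 1))
    for j, t in enumerate(terms):
        y = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            out[t] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[t] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
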