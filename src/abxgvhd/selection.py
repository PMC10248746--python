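"""Model reduction for interval-coded exposures.

Two stages mirror the fitting workflow: first, columns with perfect
separation on event occurrence (all or none of the exposed patients develop
the primary event) are merged with an adjacent same-class interval for model
stability; second, a greedy backward elimination combines adjacent-interval
exposures with similar associations (both significant with the same
coefficient sign, or both non-significant) or removes classes with no
significant association in any interval, accepting at each step the single
candidate with the largest AIC decrease and stopping when no candidate
lowers the AIC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exposure import (ExposureDesign, ExposureColumn, InvalidArgumentError,
                       drop_column, merge_columns)
from .survival import (FitResult, SeparationError, expand_counting_process,
                       fit_td_hazard)

logger = logging.getLogger(__name__)


@dataclass
class SelectionStep:
    action: str                     # "merge_intervals" | "remove_class"
    abx_class: str
    interval_indices: tuple
    aic_before: float
    aic_after: float
    accepted: bool

    def __post_init__(self):
        if self.accepted and not (self.aic_after < self.aic_before):
            raise InvalidArgumentError(
                "accepted step must strictly decrease AIC")


@dataclass
class SelectionTrace:
    steps: list = field(default_factory=list)
    initial_fit: FitResult | None = None
    final_fit: FitResult | None = None

    @property
    def accepted_steps(self) -> list:
        return [s for s in self.steps if s.accepted]

    def to_dict(self) -> dict:
        return {"steps": [asdict(s) for s in self.steps],
                "initial_aic": self.initial_fit.aic if self.initial_fit else None,
                "final_aic": self.final_fit.aic if self.final_fit else None}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)


def detect_perfect_separation(design: ExposureDesign, outcomes: pd.DataFrame,
                              horizon: int = 180) -> list[str]:
    """Columns where all, or none, of the exposed patients had the primary event.

    A patient counts as exposed on a column if the column switches on at or
    before the end of their follow-up.  Columns with zero exposed patients
    are not flagged (they are degenerate, handled at fit time).
    """
    out = outcomes.set_index("patient_id")
    stop = np.minimum(out.loc[design.patients, "event_day"].to_numpy(), horizon)
    event = ((out.loc[design.patients, "event_type"] == "agvhd").to_numpy()
             & (out.loc[design.patients, "event_day"].to_numpy() <= horizon))
    flagged = []
    for col in design.columns:
        fd = design.first_day[col.label].to_numpy()
        exposed = ~np.isnan(fd) & (fd <= stop)
        if exposed.sum() == 0:
            continue
        ev = event[exposed]
        if ev.all() or not ev.any():
            flagged.append(col.label)
    return flagged


def resolve_separation(design: ExposureDesign, outcomes: pd.DataFrame,
                       horizon: int = 180,
                       fitter=None) -> tuple[ExposureDesign, list[dict]]:
    """Merge separated columns with adjacent same-class intervals until clean.

    The earlier adjacent interval is tried first; when both neighbours exist
    and ``fitter`` (a callable design -> FitResult) is supplied, the merge
    with the lower refit AIC wins.  A fully merged class still separated is
    dropped with a logged warning.  Returns the resolved design and a log of
    actions taken.
    """
    actions = []
    current = design
    for _ in range(design.n_columns + 1):
        flagged = detect_perfect_separation(current, outcomes, horizon)
        if not flagged:
            break
        label = flagged[0]
        col = next(c for c in current.columns if c.label == label)
        cls_cols = sorted((c for c in current.columns
                           if c.abx_class == col.abx_class),
                          key=lambda c: c.interval_indices[0])
        i = cls_cols.index(col)
        if len(cls_cols) == 1:
            logger.warning("class %r fully merged but still separated: "
                           "dropping column %r", col.abx_class, label)
            current = drop_column(current, label)
            actions.append({"action": "drop", "label": label})
            continue
        neighbours = []
        if i > 0:
            neighbours.append(cls_cols[i - 1])
        if i + 1 < len(cls_cols):
            neighbours.append(cls_cols[i + 1])
        if len(neighbours) == 2 and fitter is not None:
            aics = []
            for nb in neighbours:
                idx = tuple(sorted(set(col.interval_indices)
                                   | set(nb.interval_indices)))
                try:
                    aics.append(fitter(merge_columns(
                        current, col.abx_class, idx)).aic)
                except (SeparationError, InvalidArgumentError):
                    aics.append(np.inf)
            chosen = neighbours[int(np.argmin(aics))]
        else:
            chosen = neighbours[0]
        idx = tuple(sorted(set(col.interval_indices)
                           | set(chosen.interval_indices)))
        current = merge_columns(current, col.abx_class, idx)
        actions.append({"action": "merge", "abx_class": col.abx_class,
                        "interval_indices": list(idx)})
    return current, actions


def _derived_matrix(master: pd.DataFrame, columns: list[ExposureColumn],
                    base_of: dict) -> pd.DataFrame:
    """Candidate-design term columns as element-wise maxima of base columns."""
    out = master.copy()
    labels = []
    for col in columns:
        bases = base_of[col]
        lab = col.label
        labels.append(lab)
        if lab not in out.columns:
            out[lab] = np.maximum.reduce(
                [master[b].to_numpy(float) for b in bases])
    return out, labels


def backward_eliminate(design: ExposureDesign, outcomes: pd.DataFrame,
                       covariates: pd.DataFrame | None = None,
                       horizon: int = 180, alpha: float = 0.05,
                       ties: str = "efron", fine_gray: bool = True,
                       robust: bool = False):
    """Greedy AIC-guided backward elimination of interval-coded exposures.

    Candidate steps at each iteration: (a) merge an adjacent same-class
    interval pair whose two terms are similar (both p < alpha with the same
    coefficient sign, or both p >= alpha); (b) remove a class with p >= alpha
    in every interval.  The candidate with the lowest refit AIC is accepted
    if it is strictly below the current AIC; otherwise selection stops.
    Candidates are evaluated in catalogue order, intervals chronologically;
    AIC ties go to the earliest candidate.  Steps whose refit fails to
    converge are skipped and logged.

    Under persistent coding a merged column's path is the element-wise OR of
    its members, so all candidate fits reuse one master expansion; transient
    designs are re-expanded per candidate.

    Returns ``(final_fit, trace, final_columns)`` where ``final_columns`` is
    the surviving list of :class:`ExposureColumn`.
    """
    cov_cols = list(covariates.columns) if covariates is not None else []
    persistent = design.coding == "persistent"
    master = expand_counting_process(design, covariates, outcomes,
                                     horizon=horizon, fine_gray=fine_gray)
    base_of = {c: (c.label,) for c in design.columns}

    def fit_columns(columns, bases):
        if persistent:
            frame, labels = _derived_matrix(master, columns, bases)
        else:
            d2 = design.copy()
            d2.columns = list(columns)
            fd = pd.DataFrame(index=design.first_day.index)
            for col in columns:
                fd[col.label] = design.first_day[list(bases[col])].min(axis=1)
            d2.first_day = fd
            frame = expand_counting_process(d2, covariates, outcomes,
                                            horizon=horizon,
                                            fine_gray=fine_gray)
            labels = [c.label for c in columns]
        return fit_td_hazard(frame, labels + cov_cols, ties=ties,
                             robust_cluster="patient_id" if robust else None)

    columns = list(design.columns)
    fit = fit_columns(columns, base_of)
    trace = SelectionTrace(initial_fit=fit)
    if not fit.converged:
        raise RuntimeError("initial full model did not converge")

    while True:
        pmap = dict(zip(fit.terms, fit.p_values))
        cmap = dict(zip(fit.terms, fit.coef))

        def term_p(col):
            return pmap.get(col.label, 1.0)   # degenerate columns: p := 1

        def term_sign(col):
            return np.sign(cmap.get(col.label, 0.0))

        candidates = []  # (action, cls, payload)
        for cls in design.catalogue:
            cls_cols = sorted((c for c in columns if c.abx_class == cls),
                              key=lambda c: c.interval_indices[0])
            if not cls_cols:
                continue
            for c1, c2 in zip(cls_cols, cls_cols[1:]):
                p1, p2 = term_p(c1), term_p(c2)
                both_sig_same = (p1 < alpha and p2 < alpha
                                 and term_sign(c1) == term_sign(c2))
                both_nonsig = p1 >= alpha and p2 >= alpha
                if both_sig_same or both_nonsig:
                    candidates.append(("merge_intervals", cls, (c1, c2)))
            if all(term_p(c) >= alpha for c in cls_cols):
                candidates.append(("remove_class", cls, tuple(cls_cols)))

        best = None
        for action, cls, payload in candidates:
            if action == "merge_intervals":
                c1, c2 = payload
                idx = tuple(sorted(set(c1.interval_indices)
                                   | set(c2.interval_indices)))
                newcol = ExposureColumn(cls, idx)
                cand_cols = []
                inserted = False
                for c in columns:
                    if c in (c1, c2):
                        if not inserted:
                            cand_cols.append(newcol)
                            inserted = True
                    else:
                        cand_cols.append(c)
                cand_bases = dict(base_of)
                cand_bases[newcol] = tuple(base_of[c1]) + tuple(base_of[c2])
            else:
                idx = tuple(sorted(i for c in payload
                                   for i in c.interval_indices))
                cand_cols = [c for c in columns if c not in payload]
                cand_bases = {c: base_of[c] for c in cand_cols}
            try:
                cand_fit = fit_columns(cand_cols, cand_bases)
            except SeparationError as exc:
                logger.warning("candidate %s %s skipped: %s", action, cls, exc)
                continue
            if not cand_fit.converged:
                logger.warning("candidate %s %s skipped: non-convergence",
                               action, cls)
                continue
            accepted_possible = cand_fit.aic < fit.aic
            trace.steps.append(SelectionStep(
                action, cls, idx, fit.aic, cand_fit.aic, False))
            if accepted_possible and (best is None
                                      or cand_fit.aic < best[0].aic):
                best = (cand_fit, action, cls, idx, cand_cols, cand_bases)

        if best is None:
            break
        cand_fit, action, cls, idx, columns, base_of = best
        trace.steps.append(SelectionStep(
            action, cls, idx, fit.aic, cand_fit.aic, True))
        fit = cand_fit

    trace.final_fit = fit
    return fit, trace, columns


def significant_antibiotic_terms(fit: FitResult, columns, alpha: float = 0.05):
    """Antibiotic terms significant in a final model (for the restricted
    severe-grade workflow, which carries over only these terms)."""
    labels = {c.label for c in columns}
    return [t for t, p in zip(fit.terms, fit.p_values)
            if t in labels and p < alpha]
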