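"""Interval-coded, time-dependent antibiotic exposure designs.

Raw inputs are long-format person-day administration records (patient id,
integer day relative to transplant, antibiotic class).  The models consume a
binary time-dependent design with one column per (antibiotic class x
exposure interval): a patient's column switches from 0 to 1 at the first
administration day of that class inside that interval.

Two codings are supported:

* ``persistent`` (default): once a column switches on it stays on for the
  rest of follow-up, so each class-interval term carries its own
  log-hazard-ratio from first in-interval exposure onward.
* ``transient``: the indicator is active only from the first in-interval
  administration through the end of the column's interval span.

Day 0 is the transplant day; intervals are inclusive on both ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The default antibiotic catalogue: 17 classes, with third-or-higher
#: generation cephalosporins and penicillins each split by the presence of a
#: beta-lactamase inhibitor, and vancomycin split by route.
DEFAULT_CATALOGUE: tuple[str, ...] = (
    "aminoglycosides",
    "aztreonam",
    "carbapenems",
    "cephalosporins_gen12",
    "cephalosporins_gen3plus_bli",
    "cephalosporins_gen3plus",
    "dalfopristin_quinupristin",
    "fluoroquinolones",
    "linezolid",
    "macrolides",
    "penicillins_bli",
    "penicillins",
    "rifaximin",
    "tetracyclines",
    "tmp_smx",
    "vancomycin_iv",
    "vancomycin_po",
)


class InvalidArgumentError(ValueError):
    """Raised when an operation is called with arguments violating its contract."""


def validate_catalogue(catalogue) -> tuple[str, ...]:
    cat = tuple(catalogue)
    if not cat:
        raise InvalidArgumentError("antibiotic catalogue must be non-empty")
    if len(set(cat)) != len(cat):
        raise InvalidArgumentError("antibiotic class names must be unique")
    return cat


@dataclass(frozen=True)
class IntervalScheme:
    """Ordered, contiguous, non-overlapping inclusive day ranges."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.intervals:
            raise InvalidArgumentError("interval scheme must have >= 1 interval")
        for (a, b) in self.intervals:
            if a > b:
                raise InvalidArgumentError(f"interval [{a},{b}] is empty")
        for (a0, b0), (a1, b1) in zip(self.intervals, self.intervals[1:]):
            if a1 != b0 + 1:
                raise InvalidArgumentError(
                    "intervals must be ordered, contiguous and non-overlapping"
                )

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    @property
    def window_start(self) -> int:
        return self.intervals[0][0]

    @property
    def window_end(self) -> int:
        return self.intervals[-1][1]

    def interval_of(self, day: int) -> int:
        """Index of the interval containing ``day`` (raises if outside the window)."""
        for k, (a, b) in enumerate(self.intervals):
            if a <= day <= b:
                return k
        raise InvalidArgumentError(f"day {day} outside window "
                                   f"[{self.window_start},{self.window_end}]")

    def to_dict(self) -> dict:
        return {"intervals": [list(iv) for iv in self.intervals]}


def build_interval_scheme(window_start: int = -7, window_end: int = 30,
                          n_intervals: int = 5) -> IntervalScheme:
    """Partition [window_start, window_end] into ``n_intervals`` contiguous ranges.

    Each interval spans ``floor(window_days / n_intervals)`` days; the final
    interval absorbs any remainder.  With the defaults (-7, 30, 5) this gives
    the canonical scheme: pre-transplant [-7,-1], then post-transplant weeks
    [0,6], [7,13], [14,20], and [21,30] (the last week absorbing days 28-30).
    """
    n_days = window_end - window_start + 1
    if n_intervals < 1:
        raise InvalidArgumentError("n_intervals must be >= 1")
    if n_days < n_intervals:
        raise InvalidArgumentError(
            f"window of {n_days} days cannot be split into {n_intervals} intervals"
        )
    base = n_days // n_intervals
    bounds = []
    start = window_start
    for k in range(n_intervals):
        end = window_end if k == n_intervals - 1 else start + base - 1
        bounds.append((start, end))
        start = end + 1
    return IntervalScheme(tuple(bounds))


@dataclass(frozen=True)
class ExposureColumn:
    """One design column: an antibiotic class over a contiguous set of intervals."""

    abx_class: str
    interval_indices: tuple[int, ...]  # sorted, contiguous

    @property
    def label(self) -> str:
        idx = self.interval_indices
        if len(idx) == 1:
            return f"{self.abx_class}__{idx[0]}"
        return f"{self.abx_class}__{idx[0]}-{idx[-1]}"


@dataclass
class ExposureDesign:
    """Per-patient binary time-dependent covariate paths.

    ``first_day`` is a (patients x columns) frame of the day each column
    switches on (NaN = never exposed).  Paths are step functions of day
    derived from ``first_day`` under the design's coding.
    """

    patients: list
    catalogue: tuple[str, ...]
    scheme: IntervalScheme
    columns: list[ExposureColumn]
    first_day: pd.DataFrame  # index=patients, columns=column labels, float
    coding: str = "persistent"  # or "transient"
    n_dropped_records: int = 0

    def __post_init__(self):
        if self.coding not in ("persistent", "transient"):
            raise InvalidArgumentError(f"unknown coding {self.coding!r}")

    @property
    def column_labels(self) -> list[str]:
        return [c.label for c in self.columns]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column_off_day(self, col: ExposureColumn):
        """First day the column is no longer active (None under persistent coding)."""
        if self.coding == "persistent":
            return None
        return self.scheme.intervals[col.interval_indices[-1]][1] + 1

    def path_value(self, patient, label: str, day: int) -> int:
        """The 0/1 value of a column's step function on a given day."""
        fd = self.first_day.at[patient, label]
        if np.isnan(fd) or day < fd:
            return 0
        col = next(c for c in self.columns if c.label == label)
        off = self.column_off_day(col)
        return 1 if off is None or day < off else 0

    def switch_days(self, patient) -> dict[str, tuple[int, int | None]]:
        """Per exposed column: (on day, off day or None) for one patient."""
        out = {}
        row = self.first_day.loc[patient]
        for col in self.columns:
            fd = row[col.label]
            if not np.isnan(fd):
                out[col.label] = (int(fd), self.column_off_day(col))
        return out

    def copy(self) -> "ExposureDesign":
        return replace(self, columns=list(self.columns),
                       first_day=self.first_day.copy())


def encode_exposures(records: pd.DataFrame, scheme: IntervalScheme,
                     catalogue=DEFAULT_CATALOGUE,
                     coding: str = "persistent",
                     patients=None) -> ExposureDesign:
    """Encode long-format administration records into an interval design.

    ``records`` needs columns ``patient_id, day, abx_class``; duplicate
    administration days collapse to one, out-of-window days are dropped with a
    logged count, unknown class names are an error.  ``patients`` is the
    cohort roster (never-exposed patients have all-zero paths but still enter
    risk sets); by default the patients appearing in ``records``.
    """
    catalogue = validate_catalogue(catalogue)
    req = {"patient_id", "day", "abx_class"}
    if not req.issubset(records.columns):
        raise InvalidArgumentError(f"records must have columns {sorted(req)}")
    records = records.drop_duplicates(subset=["patient_id", "day", "abx_class"])
    unknown = sorted(set(records["abx_class"]) - set(catalogue))
    if unknown:
        raise InvalidArgumentError(f"unknown antibiotic classes: {unknown}")

    in_window = records["day"].between(scheme.window_start, scheme.window_end)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.warning("dropped %d administration records outside window [%d,%d]",
                       n_dropped, scheme.window_start, scheme.window_end)
    records = records[in_window]

    if patients is None:
        patients = sorted(records["patient_id"].unique().tolist())
    else:
        patients = list(patients)
        extra = set(records["patient_id"]) - set(patients)
        if extra:
            raise InvalidArgumentError(
                f"records for patients outside the roster: {sorted(extra)[:5]}")
    columns = [ExposureColumn(cls, (k,))
               for cls in catalogue for k in range(scheme.n_intervals)]
    first = pd.DataFrame(np.nan, index=patients,
                         columns=[c.label for c in columns], dtype=float)
    if len(records):
        rec = records.copy()
        rec["interval"] = rec["day"].map(scheme.interval_of)
        grouped = rec.groupby(["patient_id", "abx_class", "interval"])["day"].min()
        for (pid, cls, k), day in grouped.items():
            first.at[pid, f"{cls}__{k}"] = float(day)
    return ExposureDesign(patients=patients, catalogue=catalogue, scheme=scheme,
                          columns=columns, first_day=first, coding=coding,
                          n_dropped_records=n_dropped)


def empty_design(patients, scheme: IntervalScheme,
                 catalogue=DEFAULT_CATALOGUE,
                 coding: str = "persistent") -> ExposureDesign:
    """An all-zero design over the given patients (no administrations)."""
    catalogue = validate_catalogue(catalogue)
    columns = [ExposureColumn(cls, (k,))
               for cls in catalogue for k in range(scheme.n_intervals)]
    first = pd.DataFrame(np.nan, index=list(patients),
                         columns=[c.label for c in columns], dtype=float)
    return ExposureDesign(patients=list(patients), catalogue=catalogue,
                          scheme=scheme, columns=columns, first_day=first,
                          coding=coding)


def merge_columns(design: ExposureDesign, abx_class: str,
                  interval_indices) -> ExposureDesign:
    """Replace a class's columns over contiguous intervals by a single column.

    The merged column switches on at the earliest first-exposure day among the
    merged columns; all other columns are unchanged.
    """
    idx = tuple(sorted(set(int(i) for i in interval_indices)))
    if len(idx) < 2:
        raise InvalidArgumentError("merge needs >= 2 interval indices")
    # contiguity is judged on the class's current column layout: each current
    # column owns a contiguous run of original interval indices
    targets = [c for c in design.columns
               if c.abx_class == abx_class and set(c.interval_indices) <= set(idx)]
    covered = sorted(i for c in targets for i in c.interval_indices)
    if covered != list(range(idx[0], idx[-1] + 1)) or set(covered) != set(idx):
        raise InvalidArgumentError(
            f"interval indices {idx} are not a contiguous set of current "
            f"columns for class {abx_class!r}")
    new_col = ExposureColumn(abx_class, idx)
    merged_first = design.first_day[[c.label for c in targets]].min(axis=1)

    out = design.copy()
    pos = min(out.columns.index(c) for c in targets)
    for c in targets:
        out.columns.remove(c)
    out.columns.insert(pos, new_col)
    out.first_day = out.first_day.drop(columns=[c.label for c in targets])
    out.first_day.insert(min(pos, out.first_day.shape[1]), new_col.label,
                         merged_first)
    return out


def drop_column(design: ExposureDesign, label: str) -> ExposureDesign:
    out = design.copy()
    out.columns = [c for c in out.columns if c.label != label]
    out.first_day = out.first_day.drop(columns=[label])
    return out


# ---------------------------------------------------------------------------
# i/o

def read_exposure_records(path) -> pd.DataFrame:
    """Read the long administration CSV (`patient_id,day,abx_class`)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "abx_class": str})
    df["day"] = df["day"].astype(int)
    return df


def person_day_frame(design: ExposureDesign, days=None) -> pd.DataFrame:
    """Wide person-day 0/1 matrix (`patient_id,day,<class>__<interval>,...`)."""
    if days is None:
        days = range(design.scheme.window_start, design.scheme.window_end + 1)
    days = np.asarray(list(days))
    rows = []
    fd = design.first_day
    offs = {c.label: design.column_off_day(c) for c in design.columns}
    for pid in design.patients:
        vals = fd.loc[pid].to_numpy()
        on = (days[:, None] >= vals[None, :])
        for j, c in enumerate(design.columns):
            off = offs[c.label]
            if off is not None:
                on[:, j] &= days < off
        block = pd.DataFrame(on.astype(int), columns=design.column_labels)
        block.insert(0, "day", days)
        block.insert(0, "patient_id", pid)
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def write_design(design: ExposureDesign, csv_path, json_path) -> None:
    """Serialize to a wide person-day CSV plus a JSON sidecar (scheme, catalogue)."""
    person_day_frame(design).to_csv(csv_path, index=False)
    meta = {"scheme": design.scheme.to_dict(),
            "catalogue": list(design.catalogue),
            "coding": design.coding,
            "columns": [{"abx_class": c.abx_class,
                         "interval_indices": list(c.interval_indices)}
                        for c in design.columns]}
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def design_to_records(design: ExposureDesign) -> pd.DataFrame:
    """Long records reconstructing the design's first-exposure days.

    One record per exposed (patient, column) at its switch-on day; re-encoding
    these records reproduces the paths of an unmerged design exactly.
    """
    rows = []
    for pid in design.patients:
        for label, (on, _off) in design.switch_days(pid).items():
            cls = label.split("__")[0]
            rows.append((pid, on, cls))
    return pd.DataFrame(rows, columns=["patient_id", "day", "abx_class"])
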