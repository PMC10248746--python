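#!/usr/bin/env python
"""Encode the simulated administration records into the interval design.

Demonstrates the structural arithmetic of the design: 17 antibiotic classes
by 5 exposure intervals give 85 binary time-dependent columns, and together
with the 9 nonantibiotic covariate terms the full model carries 94
variables.  Requires 01_simulate_cohorts.py to have run (reads the `null`
scenario cohort from scratch/).
"""

import json
import pathlib

from abxgvhd.exposure import (DEFAULT_CATALOGUE, build_interval_scheme,
                              encode_exposures, read_exposure_records,
                              write_design)
from abxgvhd.survival import covariate_model_matrix, read_covariates, read_outcomes

ROOT = pathlib.Path(__file__).resolve().parents[1]
cohort = ROOT / "scratch" / "cohorts" / "null"

outcomes = read_outcomes(cohort / "outcomes.csv")
records = read_exposure_records(cohort / "exposures.csv")
scheme = build_interval_scheme(-7, 30, 5)
design = encode_exposures(records, scheme,
                          patients=sorted(outcomes["patient_id"]))
cov = covariate_model_matrix(read_covariates(cohort / "covariates.csv"))

write_design(design, ROOT / "scratch" / "design_person_day.csv",
             ROOT / "scratch" / "design_meta.json")

summary = {
    "interval_boundaries": [list(iv) for iv in scheme.intervals],
    "n_classes": len(DEFAULT_CATALOGUE),
    "n_intervals": scheme.n_intervals,
    "n_exposure_columns": design.n_columns,
    "n_covariate_terms": int(cov.shape[1]),
    "n_model_variables": design.n_columns + int(cov.shape[1]),
    "n_patients": len(design.patients),
    "n_dropped_out_of_window_records": design.n_dropped_records,
}
with open(ROOT / "results" / "design_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1)
print(json.dumps(summary, indent=1))
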