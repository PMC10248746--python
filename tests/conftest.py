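import numpy as np
import pandas as pd
import pytest

from abxgvhd.exposure import build_interval_scheme, encode_exposures


@pytest.fixture
def scheme():
    return build_interval_scheme(-7, 30, 5)


@pytest.fixture
def covariate_table():
    """Six-patient baseline table covering every declared level."""
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(6)],
        "graft_source": ["pbsc", "bone_marrow", "cord_blood",
                         "pbsc", "pbsc", "bone_marrow"],
        "conditioning_intensity": ["myeloablative", "reduced_intensity"] * 3,
        "atg_use": ["no", "yes", "no", "no", "yes", "no"],
        "donor_type": ["related", "unrelated"] * 3,
        "gvhd_prophylaxis": ["cni_based", "ptcy_based"] * 3,
        "engrafted": [True, True, True, True, True, False],
        "engraftment_day": [14.0, 17.0, 20.0, 15.0, 19.0, np.nan],
    }).set_index("patient_id")


def make_records(rows):
    return pd.DataFrame(rows, columns=["patient_id", "day", "abx_class"])


def make_outcomes(rows):
    return pd.DataFrame(rows, columns=["patient_id", "event_day", "event_type"])


@pytest.fixture
def tiny_catalogue():
    return ("carbapenems", "fluoroquinolones")


@pytest.fixture
def simple_design(scheme, tiny_catalogue):
    """Three patients: one carbapenem day 3, one FQ day -2, one unexposed."""
    rec = make_records([("a", 3, "carbapenems"), ("b", -2, "fluoroquinolones")])
    return encode_exposures(rec, scheme, tiny_catalogue,
                            patients=["a", "b", "c"])
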