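import numpy as np
import pandas as pd
import pytest


def make_record(**overrides):
    """One clean, eligible patient record as a dict."""
    rec = {
        "patient_id": "P0",
        "age": 64,
        "sex": "female",
        "race": "non-Hispanic white",
        "marital_status": "married",
        "year_dx": 2010,
        "hsa_id": "HSA000",
        "site_code": "C187",
        "histology_code": 8140,
        "histology_confirmed": True,
        "prior_malignancy": False,
        "autopsy_only": False,
        "surgery_primary": "yes",
        "surgery_mets": "no",
        "followup_months": 12.0,
        "event": True,
        "tumor_size": "unknown",
        "grade": "1-2",
        "t_stage": "T3-4",
        "n_stage": "N1-2",
    }
    rec.update(overrides)
    return rec


@pytest.fixture
def record_frame():
    """Factory: build a cohort frame from per-record overrides."""
    def build(rows):
        return pd.DataFrame([make_record(patient_id=f"P{i}", **r)
                             for i, r in enumerate(rows)])
    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
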