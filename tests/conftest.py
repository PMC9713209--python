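import numpy as np
import pandas as pd
import pytest

from chimwatch import Cohort, cohort_from_frames


def make_cohort(transplants, measurements, validate=True) -> Cohort:
    """Build a cohort from sparse record dicts, filling sensible
    defaults for fields a test does not care about."""
    t_rows = []
    for rec in transplants:
        row = {
            "transplant_id": rec["transplant_id"],
            "patient_id": rec.get("patient_id", rec["transplant_id"]),
            "age_years": rec.get("age_years", 40.0),
            "relapse_day": rec.get("relapse_day"),
            "censor_day": rec.get("censor_day", 3000),
            "conditioning": rec.get("conditioning", "MAC"),
            "atg": rec.get("atg", 0),
            "source": rec.get("source", "PB"),
            "donor": rec.get("donor", "MUD"),
        }
        t_rows.append(row)
    m_rows = []
    for rec in measurements:
        row = {
            "transplant_id": rec["transplant_id"],
            "day": rec["day"],
            "compartment": rec.get("compartment", "marrow"),
            "lineage": rec.get("lineage", "CD3"),
            "percent_recipient": rec["percent_recipient"],
            "below_detection": rec.get("below_detection", 0),
        }
        m_rows.append(row)
    t = pd.DataFrame(t_rows, columns=["transplant_id", "patient_id",
                                      "age_years", "relapse_day",
                                      "censor_day", "conditioning", "atg",
                                      "source", "donor"])
    m = pd.DataFrame(m_rows, columns=["transplant_id", "day", "compartment",
                                      "lineage", "percent_recipient",
                                      "below_detection"])
    return cohort_from_frames(t, m, validate=validate)


@pytest.fixture
def rng():
    return np.random.default_rng(20220919)
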