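import pandas as pd
import pytest

import ocuvigil as ov
from ocuvigil.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_db():
    """A small default-condition synthetic database with injected duplicates."""
    cfg = ov.default_config(n_reports=3000, seed=7, duplicate_rate=0.1)
    return ov.generate_database(cfg)


@pytest.fixture(scope="session")
def pipeline_state():
    """One full pipeline run on default study conditions."""
    cfg = PipelineConfig(synth=ov.default_config(n_reports=8000, seed=3), seed=3)
    return run_pipeline(cfg)


def make_case(
    primaryid="100000000011",
    caseid="1000000000",
    sex="F",
    age_years=60.0,
    country="US",
    fda_date="2020-06-01",
    **extra,
):
    row = {
        "primaryid": primaryid,
        "caseid": caseid,
        "sex": sex,
        "age_years": age_years,
        "country": country,
        "fda_date": pd.Timestamp(fda_date),
    }
    row.update(extra)
    return row


def make_exposure(primaryid, start_date, precision="day", drug_seq=1):
    return {
        "primaryid": primaryid,
        "drug_seq": drug_seq,
        "generic_name": "Palbociclib",
        "role_cod": "PS",
        "start_date": pd.Timestamp(start_date) if start_date else pd.NaT,
        "start_precision": precision,
    }
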