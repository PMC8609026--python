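import numpy as np
import pandas as pd
import pytest

from claimsphenotyper import load_fixture_catalog
from claimsphenotyper.dataset import ClaimsDataset


@pytest.fixture(scope="session")
def catalog():
    return load_fixture_catalog()


def make_dataset(spans, claims, demographics=None):
    """Build a small ClaimsDataset from compact tuples.

    spans:  [(pid, start, end), ...]
    claims: [(pid, day, diag_list, proc_list, rev_list[, amount[, setting]]), ...]
    """
    pids = sorted({pid for pid, *_ in spans} | {c[0] for c in claims})
    demographics = demographics or {}
    patient_rows = []
    for i, pid in enumerate(pids):
        row = {"patient_id": pid, "sex": "M", "race_ethnicity": "white",
               "census_division": "division_1", "birth_year": 2010,
               "household_children": 2}
        row.update(demographics.get(pid, {}))
        patient_rows.append(row)
    claim_rows = []
    for claim in claims:
        pid, day, diag, proc, rev = claim[:5]
        amount = claim[5] if len(claim) > 5 else 100.0
        setting = claim[6] if len(claim) > 6 else "outpatient"
        claim_rows.append((pid, int(day), list(diag), list(proc), list(rev),
                           float(amount), setting))
    patients = pd.DataFrame(patient_rows)
    enrollment = pd.DataFrame(spans, columns=["patient_id", "start_day", "end_day"])
    claims_frame = pd.DataFrame(claim_rows, columns=[
        "patient_id", "service_day", "diagnosis_codes", "procedure_codes",
        "revenue_codes", "allowed_amount", "setting"])
    return ClaimsDataset(patients, enrollment, claims_frame).validate()


@pytest.fixture
def dataset_builder():
    return make_dataset
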