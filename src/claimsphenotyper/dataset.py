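"""In-memory claims dataset and its delimited-file round trip.

All dates are "derived dates": integer days since the patient's birth (day 0 =
date of birth), the de-identified representation used by large claims
databases. A dataset is three tables:

``patients``    patient_id, sex, race_ethnicity, census_division, birth_year,
                household_children
``enrollment``  patient_id, start_day, end_day   (inclusive, non-overlapping)
``claims``      patient_id, service_day, diagnosis_codes, procedure_codes,
                revenue_codes, allowed_amount, setting

Code lists are Python lists in memory and pipe-delimited strings on disk; the
first diagnosis code on a claim is the first-listed (primary) diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DatasetValidationError, SchemaError

PATIENT_COLUMNS = ["patient_id", "sex", "race_ethnicity", "census_division",
                   "birth_year", "household_children"]
ENROLLMENT_COLUMNS = ["patient_id", "start_day", "end_day"]
CLAIM_COLUMNS = ["patient_id", "service_day", "diagnosis_codes",
                 "procedure_codes", "revenue_codes", "allowed_amount", "setting"]
SETTINGS = ("inpatient", "outpatient", "pharmacy")


@dataclass
class ClaimsDataset:
    patients: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame

    def validate(self) -> "ClaimsDataset":
        for name, frame, cols in (("patients", self.patients, PATIENT_COLUMNS),
                                  ("enrollment", self.enrollment, ENROLLMENT_COLUMNS),
                                  ("claims", self.claims, CLAIM_COLUMNS)):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise SchemaError(f"{name} table missing columns: {sorted(missing)}")
        if self.patients["patient_id"].duplicated().any():
            dupes = self.patients.loc[
                self.patients["patient_id"].duplicated(), "patient_id"].tolist()
            raise DatasetValidationError(f"duplicate patient_id: {dupes[:5]}")
        if len(self.enrollment):
            bad = self.enrollment[
                self.enrollment["start_day"] > self.enrollment["end_day"]]
            if len(bad):
                raise DatasetValidationError(
                    f"enrollment spans with start_day > end_day for patients "
                    f"{bad['patient_id'].tolist()[:5]}")
            if (self.enrollment["start_day"] < 0).any():
                raise DatasetValidationError("negative enrollment start_day")
            spans = self.enrollment.sort_values(["patient_id", "start_day"])
            prev_end = spans.groupby("patient_id")["end_day"].shift()
            overlap = spans[prev_end.notna() & (spans["start_day"] <= prev_end)]
            if len(overlap):
                raise DatasetValidationError(
                    "overlapping enrollment spans for patients "
                    f"{sorted(set(overlap['patient_id']))[:5]}")
            self.enrollment = spans.reset_index(drop=True)
        if len(self.claims):
            if (self.claims["service_day"] < 0).any():
                raise DatasetValidationError("claims with negative service_day")
            if (self.claims["allowed_amount"] < 0).any():
                raise DatasetValidationError("claims with negative allowed_amount")
            empty = ~(self.claims["diagnosis_codes"].map(bool)
                      | self.claims["procedure_codes"].map(bool)
                      | self.claims["revenue_codes"].map(bool))
            if empty.any():
                raise DatasetValidationError(
                    "claims with no codes for patients "
                    f"{self.claims.loc[empty, 'patient_id'].tolist()[:5]}")
            unknown = ~self.claims["setting"].isin(SETTINGS)
            if unknown.any():
                raise DatasetValidationError(
                    f"unknown claim settings: "
                    f"{sorted(set(self.claims.loc[unknown, 'setting']))}")
        return self

    def spans_by_patient(self) -> dict:
        """patient_id -> list of (start_day, end_day), sorted."""
        out: dict = {}
        for pid, start, end in self.enrollment[
                ["patient_id", "start_day", "end_day"]].itertuples(index=False):
            out.setdefault(pid, []).append((int(start), int(end)))
        for spans in out.values():
            spans.sort()
        return out

    def equals(self, other: "ClaimsDataset") -> bool:
        try:
            pd.testing.assert_frame_equal(
                self.patients.reset_index(drop=True),
                other.patients.reset_index(drop=True))
            pd.testing.assert_frame_equal(
                self.enrollment.reset_index(drop=True),
                other.enrollment.reset_index(drop=True))
            a = self.claims.reset_index(drop=True)
            b = other.claims.reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)
        except AssertionError:
            return False
        return True


def _join_codes(codes) -> str:
    return "|".join(str(c) for c in codes)


def _split_codes(text) -> list[str]:
    text = str(text)
    return [] if text == "" else text.split("|")


def write_dataset(dataset: ClaimsDataset, directory: str | Path) -> None:
    """Write patients/enrollment/claims CSVs; lossless with :func:`read_dataset`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.patients.to_csv(directory / "patients.csv", index=False)
    dataset.enrollment.to_csv(directory / "enrollment.csv", index=False)
    claims = dataset.claims.copy()
    for col in ("diagnosis_codes", "procedure_codes", "revenue_codes"):
        claims[col] = claims[col].map(_join_codes)
    claims["allowed_amount"] = claims["allowed_amount"].map(lambda x: f"{x:.2f}")
    claims.to_csv(directory / "claims.csv", index=False)


def read_dataset(directory: str | Path) -> ClaimsDataset:
    """Read a dataset directory and validate all invariants."""
    directory = Path(directory)
    for name in ("patients.csv", "enrollment.csv", "claims.csv"):
        if not (directory / name).exists():
            raise SchemaError(f"dataset directory {directory} missing {name}")
    patients = pd.read_csv(directory / "patients.csv",
                           dtype={"patient_id": str, "sex": str,
                                  "race_ethnicity": str, "census_division": str})
    if patients.empty:
        patients = patients.astype({"birth_year": "int64",
                                    "household_children": "int64"}, errors="ignore")
    enrollment = pd.read_csv(directory / "enrollment.csv", dtype={"patient_id": str})
    claims = pd.read_csv(directory / "claims.csv",
                         dtype={"patient_id": str, "setting": str},
                         keep_default_na=False, na_values=[])
    for col in ("diagnosis_codes", "procedure_codes", "revenue_codes"):
        claims[col] = claims[col].map(_split_codes)
    if len(claims):
        claims["service_day"] = claims["service_day"].astype(int)
        claims["allowed_amount"] = claims["allowed_amount"].astype(float)
    else:
        claims = claims.astype({"service_day": "int64",
                                "allowed_amount": "float64"}, errors="ignore")
    return ClaimsDataset(patients, enrollment, claims).validate()
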