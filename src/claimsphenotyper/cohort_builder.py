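"""Cohort construction: index events, eligibility, and population split.

Three non-mutually-exclusive case cohorts are built from a claims dataset and
a code catalog:

``broad``         any possible/probable/definite diagnosis code (excluding
                  easy-to-diagnose codes) or any curated CPT/HCPCS procedure
                  code (genetic test or other workup);
``mca_id_dd_e``   diagnosis codes for multiple congenital anomalies (an
                  MCA-specific code, or single-anomaly codes in two or more
                  organ systems), moderate/severe intellectual disability,
                  developmental delay, or epilepsy/seizures;
``conservative``  a possible or probable diagnosis code as the *index* code
                  plus at least one genetic-test procedure at any time;
                  patients whose index code is definite are excluded.

The index date is the service date of the first appearing qualifying code
(diagnosis only for the conservative and MCA/ID/DD/E cohorts; diagnosis or
procedure for broad). Within a day, diagnosis codes are preferred with a
definite > probable > possible hierarchy, then procedures; residual ties break
on the lexicographically smallest code. A code's age window is evaluated at
the claim's service day.

Eligibility requires continuous enrollment for the 180 days before the index
date, reduced to the patient's age for children younger than 6 months at
index. Cases are then split into critically-ill newborns (index <=28 days of
age plus a NICU stay at any time during the observation period, i.e. the
union of enrollment spans) and pediatric patients (everyone else up to 18
years at index). Controls are patients with no qualifying code of any kind at
any time; their index date is the start of their first enrollment span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .code_catalog import CodeCatalog
from .dataset import ClaimsDataset

COHORTS = ("broad", "mca_id_dd_e", "conservative")
LOOKBACK_DAYS = 180
NEWBORN_MAX_INDEX_DAY = 28
PEDIATRIC_MAX_INDEX_DAY = 18 * 365

# same-day tie hierarchy: diagnoses (definite > probable > possible), then tests
_CATEGORY_RANK = {"definite": 0, "probable": 1, "possible": 2,
                  "genetic_test": 3, "other_cpt_hcpcs": 4}


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_day: int
    index_code: str
    index_code_kind: str  # diagnosis | genetic_test | other_workup
    index_category: str   # possible | probable | definite | genetic_test | other_cpt_hcpcs


@dataclass
class AttritionReport:
    """Ordered (filter_label, n_remaining) chains, one per cohort."""

    steps: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(cohort, label, n)
                for cohort, chain in self.steps.items()
                for label, n in chain]
        return pd.DataFrame(rows, columns=["cohort", "filter_label", "n_remaining"])


def _claim_rows(claims: pd.DataFrame) -> list[tuple]:
    """(service_day, diagnosis_codes, procedure_codes, revenue_codes) sorted by day."""
    rows = list(claims[["service_day", "diagnosis_codes", "procedure_codes",
                        "revenue_codes"]].itertuples(index=False, name=None))
    rows.sort(key=lambda r: r[0])
    return rows


def _qualifying_candidates(rows: Iterable[tuple], catalog: CodeCatalog,
                           cohort_def: str):
    """Yield (day, category_rank, code, category, kind) for qualifying codes."""
    for day, diagnoses, procedures, _ in rows:
        age = int(day)
        for code in diagnoses:
            entry = catalog.lookup_diagnosis(code, age)
            if entry is None or entry.easy_to_diagnose:
                continue
            if cohort_def == "mca_id_dd_e":
                if not (entry.mca_specific_flag or entry.anomaly_flag
                        or entry.id_flag or entry.dd_flag or entry.e_flag):
                    continue
            yield (age, _CATEGORY_RANK[entry.tier], entry.code, entry.tier,
                   "diagnosis")
        if cohort_def == "broad":
            for code in procedures:
                category = catalog.lookup_procedure(code)
                if category is None:
                    continue
                index_category = ("genetic_test" if category == "genetic_test"
                                  else "other_cpt_hcpcs")
                yield (age, _CATEGORY_RANK[index_category], code, index_category,
                       category)


def find_index_event(patient_claims: pd.DataFrame, catalog: CodeCatalog,
                     cohort_def: str,
                     patient_id: Optional[str] = None) -> Optional[IndexEvent]:
    """First qualifying event for ``cohort_def``, or None if nothing qualifies."""
    if cohort_def not in COHORTS:
        raise ValueError(f"unknown cohort definition {cohort_def!r}")
    rows = _claim_rows(patient_claims)
    best = None
    for candidate in _qualifying_candidates(rows, catalog, cohort_def):
        key = (candidate[0], candidate[1], candidate[2])
        if best is None or key < (best[0], best[1], best[2]):
            best = candidate
    if best is None:
        return None
    day, _, code, category, kind = best
    if patient_id is None:
        patient_id = str(patient_claims["patient_id"].iloc[0]) \
            if len(patient_claims) else ""
    return IndexEvent(patient_id, day, code, kind, category)


def merge_spans(spans: list[tuple[int, int]], bridge: int = 0) -> list[tuple[int, int]]:
    """Merge sorted spans whose gaps are <= ``bridge`` days."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start - merged[-1][1] - 1 <= bridge:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def check_continuous_enrollment(spans: list[tuple[int, int]], index_day: int,
                                bridge: int = 0) -> bool:
    """True iff one span covers the pre-index lookback window with no gap.

    The required lookback is min(180, index_day) days: a child younger than
    6 months at index only needs coverage back to birth.
    """
    if index_day < 0:
        raise ValueError("index_day must be >= 0")
    lookback = min(LOOKBACK_DAYS, index_day)
    window_start = index_day - lookback
    for start, end in merge_spans(spans, bridge):
        if start <= window_start and end >= index_day:
            return True
    return False


def has_mca(patient_claims: pd.DataFrame, catalog: CodeCatalog) -> bool:
    """Multiple congenital anomalies: an MCA-specific code, or single-anomaly
    codes spanning two or more organ systems (age windows per claim day)."""
    systems = set()
    for day, diagnoses, _, _ in _claim_rows(patient_claims):
        for code in diagnoses:
            entry = catalog.lookup_diagnosis(code, int(day))
            if entry is None or entry.easy_to_diagnose:
                continue
            if entry.mca_specific_flag:
                return True
            if entry.anomaly_flag:
                systems.add(entry.organ_system)
    return len(systems) >= 2


def has_id_dd_e(patient_claims: pd.DataFrame, catalog: CodeCatalog) -> bool:
    for day, diagnoses, _, _ in _claim_rows(patient_claims):
        for code in diagnoses:
            entry = catalog.lookup_diagnosis(code, int(day))
            if entry is not None and not entry.easy_to_diagnose and (
                    entry.id_flag or entry.dd_flag or entry.e_flag):
                return True
    return False


def _has_genetic_test(rows: Iterable[tuple], catalog: CodeCatalog) -> bool:
    for _, _, procedures, _ in rows:
        for code in procedures:
            if catalog.lookup_procedure(code) == "genetic_test":
                return True
    return False


def _has_nicu_stay(rows: Iterable[tuple], catalog: CodeCatalog,
                   spans: list[tuple[int, int]]) -> bool:
    """>=1 claim with a NICU revenue code inside the observation period."""
    for day, _, _, revenues in rows:
        if any(catalog.revenue_unit(code) == "NICU" for code in revenues):
            if any(s <= day <= e for s, e in spans):
                return True
    return False


def assign_cohorts(dataset: ClaimsDataset, catalog: CodeCatalog,
                   require_enrollment: bool = True,
                   gap_bridge: int = 0) -> tuple[pd.DataFrame, AttritionReport]:
    """Per-patient cohort membership, population, and attrition counts.

    Each cohort has its own index event and is eligibility-checked at its own
    index date. Conservative and MCA/ID/DD/E membership additionally requires
    Broad membership (the subset structure of the study design). Returns a
    one-row-per-patient frame with flags, per-cohort index fields, population
    and exclusion reason, plus an :class:`AttritionReport`.
    """
    spans_by_patient = dataset.spans_by_patient()
    claims_by_patient = {pid: group for pid, group
                         in dataset.claims.groupby("patient_id", sort=False)}
    empty_claims = dataset.claims.iloc[0:0]

    counters = {c: {"has_qualifying_index": 0, "continuous_enrollment": 0,
                    "age_at_index_within_range": 0, "meets_cohort_definition": 0}
                for c in COHORTS}
    records = []
    for pid in dataset.patients["patient_id"]:
        pid = str(pid)
        claims = claims_by_patient.get(pid, empty_claims)
        rows = _claim_rows(claims)
        spans = spans_by_patient.get(pid, [])

        events = {c: find_index_event(claims, catalog, c, patient_id=pid)
                  for c in COHORTS}
        enrolled = {}
        in_range = {}
        for c, event in events.items():
            if event is None:
                enrolled[c] = False
                in_range[c] = False
                continue
            counters[c]["has_qualifying_index"] += 1
            enrolled[c] = (not require_enrollment) or check_continuous_enrollment(
                spans, event.index_day, bridge=gap_bridge)
            if enrolled[c]:
                counters[c]["continuous_enrollment"] += 1
            in_range[c] = enrolled[c] and event.index_day <= PEDIATRIC_MAX_INDEX_DAY
            if in_range[c]:
                counters[c]["age_at_index_within_range"] += 1

        record: dict = {"patient_id": pid}
        for c, event in events.items():
            prefix = c
            record[f"{prefix}_index_day"] = np.nan if event is None else event.index_day
            record[f"{prefix}_index_code"] = "" if event is None else event.index_code
            record[f"{prefix}_index_category"] = ("" if event is None
                                                  else event.index_category)

        in_broad = in_range["broad"]
        in_mca = (in_range["mca_id_dd_e"] and in_broad
                  and (has_mca(claims, catalog) or has_id_dd_e(claims, catalog)))
        in_cons = (in_range["conservative"] and in_broad
                   and events["conservative"] is not None
                   and events["conservative"].index_category in ("possible",
                                                                 "probable")
                   and _has_genetic_test(rows, catalog))
        for c, flag in (("broad", in_broad), ("mca_id_dd_e", in_mca),
                        ("conservative", in_cons)):
            if flag:
                counters[c]["meets_cohort_definition"] += 1

        record.update(in_broad=in_broad, in_mca_id_dd_e=in_mca,
                      in_conservative=in_cons)
        record["has_nicu_stay"] = _has_nicu_stay(rows, catalog, spans)

        if events["broad"] is None:
            # no qualifying code of any kind ever -> control candidate
            if spans:
                record.update(population="control", exclusion_reason="",
                              index_day=spans[0][0], index_code="",
                              index_category="control")
            else:
                record.update(population="excluded",
                              exclusion_reason="no_enrollment",
                              index_day=np.nan, index_code="", index_category="")
        else:
            event = events["broad"]
            record.update(index_day=float(event.index_day),
                          index_code=event.index_code,
                          index_category=event.index_category)
            if event.index_day > PEDIATRIC_MAX_INDEX_DAY:
                record.update(population="excluded",
                              exclusion_reason="age_over_18_at_index",
                              in_broad=False, in_mca_id_dd_e=False,
                              in_conservative=False)
            elif not in_broad:
                record.update(population="excluded",
                              exclusion_reason="continuous_enrollment",
                              in_mca_id_dd_e=False, in_conservative=False)
            else:
                record.update(population="", exclusion_reason="")
        records.append(record)

    assignments = pd.DataFrame(records)
    assignments = split_populations(assignments, dataset, catalog)

    report = AttritionReport()
    n_total = len(dataset.patients)
    for c in COHORTS:
        chain = [("total_patients", n_total)]
        for label in ("has_qualifying_index", "continuous_enrollment",
                      "age_at_index_within_range", "meets_cohort_definition"):
            chain.append((label, counters[c][label]))
        report.steps[c] = chain
    return assignments, report


def split_populations(assignments: pd.DataFrame, dataset: ClaimsDataset,
                      catalog: CodeCatalog) -> pd.DataFrame:
    """Set population for case rows: critically-ill newborn vs pediatric.

    A critically-ill newborn is <=28 days of age at the (broad) index date
    with a NICU stay at any time during the observation period; every other
    case up to 18 years at index is pediatric. Control/excluded rows are left
    untouched.
    """
    assignments = assignments.copy()
    if "has_nicu_stay" not in assignments.columns:
        spans_by_patient = dataset.spans_by_patient()
        claims_by_patient = {pid: group for pid, group
                             in dataset.claims.groupby("patient_id", sort=False)}
        empty = dataset.claims.iloc[0:0]
        assignments["has_nicu_stay"] = [
            _has_nicu_stay(_claim_rows(claims_by_patient.get(str(pid), empty)),
                           catalog, spans_by_patient.get(str(pid), []))
            for pid in assignments["patient_id"]]
    is_case = assignments["in_broad"] | assignments["in_mca_id_dd_e"] \
        | assignments["in_conservative"]
    newborn = is_case & (assignments["index_day"] <= NEWBORN_MAX_INDEX_DAY) \
        & assignments["has_nicu_stay"]
    assignments.loc[is_case, "population"] = "pediatric"
    assignments.loc[newborn, "population"] = "critically_ill_newborn"
    return assignments


def cohort_index_frame(assignments: pd.DataFrame, cohort: str,
                       population: Optional[str] = None) -> pd.DataFrame:
    """patient_id / index_day / index_category for one cohort (optionally one
    population), using that cohort's own index event."""
    if cohort == "control":
        mask = assignments["population"] == "control"
        frame = assignments.loc[mask, ["patient_id", "index_day"]].copy()
        frame["index_category"] = "control"
    else:
        if cohort not in COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        mask = assignments[f"in_{cohort}"]
        if population is not None:
            mask = mask & (assignments["population"] == population)
        frame = assignments.loc[mask, ["patient_id", f"{cohort}_index_day",
                                       f"{cohort}_index_category"]].copy()
        frame.columns = ["patient_id", "index_day", "index_category"]
    frame["index_day"] = frame["index_day"].astype(int)
    return frame.reset_index(drop=True)
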