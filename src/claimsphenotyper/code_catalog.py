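"""Curated code catalog: the classification substrate of the pipeline.

Administrative claims identify clinical events only through billing codes.
The catalog maps

* diagnosis codes (ICD-9 / ICD-10) to a genetic-disease likelihood *tier*
  (``possible`` ~10-30%, ``probable`` >30%, ``definite`` = a named genetic
  disease), with flags for congenital anomalies, multiple-congenital-anomaly
  (MCA) specific codes, intellectual disability (ID), developmental delay (DD)
  and epilepsy/seizures (E), an "easy to diagnose" marker for conditions with
  established targeted diagnostics, and an age-of-presentation window in days
  since birth (e.g. isolated scoliosis suggests a genetic disorder in a
  newborn but not in an adolescent);
* procedure codes (CPT / HCPCS) to ``genetic_test`` vs ``other_workup``;
* revenue codes to the intensive-care unit they bill (NICU / PICU).

The catalog is data, not code: the repository ships a small fixture catalog
covering every tier/flag/category so the pipeline is fully exercisable, and a
production analysis supplies its own file with the same schema.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import CatalogValidationError, SchemaError

logger = logging.getLogger(__name__)

TIERS = ("possible", "probable", "definite")
TIER_RANK = {"possible": 0, "probable": 1, "definite": 2}
DIAGNOSIS_SYSTEMS = ("ICD10", "ICD9")  # lookup preference order for bare codes
PROCEDURE_SYSTEMS = ("CPT", "HCPCS")
PROCEDURE_CATEGORIES = ("genetic_test", "other_workup")
ICU_UNITS = ("NICU", "PICU")

CATALOG_COLUMNS = [
    "kind", "code", "code_system", "tier", "easy_to_diagnose",
    "clinical_presentation_group", "organ_system", "anomaly_flag",
    "mca_specific_flag", "id_flag", "dd_flag", "e_flag",
    "age_min_days", "age_max_days", "category", "unit",
]


def normalize_code(code: str) -> str:
    """Normalize a billing code for exact matching: uppercase, periods stripped."""
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class DiagnosisCodeEntry:
    code: str
    code_system: str  # ICD9 | ICD10
    tier: str  # possible | probable | definite
    easy_to_diagnose: bool = False
    clinical_presentation_group: str = ""
    organ_system: str = ""
    anomaly_flag: bool = False
    mca_specific_flag: bool = False
    id_flag: bool = False
    dd_flag: bool = False
    e_flag: bool = False
    age_min_days: int = 0
    age_max_days: Optional[int] = None  # None = unbounded

    def in_age_window(self, age_days: int) -> bool:
        if age_days < self.age_min_days:
            return False
        return self.age_max_days is None or age_days <= self.age_max_days

    def validate(self) -> None:
        if self.tier not in TIERS:
            raise CatalogValidationError(
                f"diagnosis code {self.code}: unknown tier {self.tier!r}")
        if self.code_system not in DIAGNOSIS_SYSTEMS:
            raise CatalogValidationError(
                f"diagnosis code {self.code}: unknown code_system {self.code_system!r}")
        if self.age_min_days < 0:
            raise CatalogValidationError(
                f"diagnosis code {self.code}: negative age_min_days")
        if self.age_max_days is not None and self.age_min_days > self.age_max_days:
            raise CatalogValidationError(
                f"diagnosis code {self.code}: vacuous age window "
                f"[{self.age_min_days}, {self.age_max_days}]")
        if self.mca_specific_flag and not self.anomaly_flag:
            raise CatalogValidationError(
                f"diagnosis code {self.code}: mca_specific_flag requires anomaly_flag")


@dataclass(frozen=True)
class ProcedureCodeEntry:
    code: str
    code_system: str  # CPT | HCPCS
    category: str  # genetic_test | other_workup

    def validate(self) -> None:
        if self.code_system not in PROCEDURE_SYSTEMS:
            raise CatalogValidationError(
                f"procedure code {self.code}: unknown code_system {self.code_system!r}")
        if self.category not in PROCEDURE_CATEGORIES:
            raise CatalogValidationError(
                f"procedure code {self.code}: unknown category {self.category!r}")


@dataclass(frozen=True)
class RevenueCodeEntry:
    code: str
    unit: str  # NICU | PICU

    def validate(self) -> None:
        if self.unit not in ICU_UNITS:
            raise CatalogValidationError(
                f"revenue code {self.code}: unknown unit {self.unit!r}")


@dataclass
class CodeCatalog:
    """Validated, queryable collection of curated code entries."""

    diagnosis_entries: list[DiagnosisCodeEntry]
    procedure_entries: list[ProcedureCodeEntry]
    revenue_entries: list[RevenueCodeEntry]
    organ_system_vocabulary: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for e in self.diagnosis_entries:
            e.validate()
        for e in self.procedure_entries:
            e.validate()
        for e in self.revenue_entries:
            e.validate()
        self._diag: dict[tuple[str, str], DiagnosisCodeEntry] = {}
        for e in self.diagnosis_entries:
            key = (normalize_code(e.code), e.code_system)
            if key in self._diag:
                raise CatalogValidationError(
                    f"duplicate diagnosis code {e.code} ({e.code_system})")
            self._diag[key] = e
        self._proc: dict[tuple[str, str], ProcedureCodeEntry] = {}
        for e in self.procedure_entries:
            key = (normalize_code(e.code), e.code_system)
            if key in self._proc:
                raise CatalogValidationError(
                    f"duplicate procedure code {e.code} ({e.code_system})")
            self._proc[key] = e
        self._rev: dict[str, RevenueCodeEntry] = {}
        for e in self.revenue_entries:
            code = normalize_code(e.code)
            if code in self._rev:
                raise CatalogValidationError(f"duplicate revenue code {e.code}")
            self._rev[code] = e
        referenced = {e.organ_system for e in self.diagnosis_entries if e.organ_system}
        if not self.organ_system_vocabulary:
            self.organ_system_vocabulary = set(referenced)
        missing = referenced - self.organ_system_vocabulary
        if missing:
            raise CatalogValidationError(
                f"organ systems referenced but not in vocabulary: {sorted(missing)}")

    # -- diagnosis ---------------------------------------------------------

    def diagnosis_entry(self, code: str, code_system: str) -> Optional[DiagnosisCodeEntry]:
        return self._diag.get((normalize_code(code), code_system))

    def classify_diagnosis(self, code: str, code_system: str,
                           age_days: int) -> Optional[str]:
        """Tier of ``code`` at ``age_days``, or None if unknown / out of window.

        Pure function of its arguments; never raises for unknown codes.
        """
        if age_days < 0:
            raise ValueError(f"age_days must be >= 0, got {age_days}")
        entry = self.diagnosis_entry(code, code_system)
        if entry is None or not entry.in_age_window(age_days):
            return None
        return entry.tier

    def lookup_diagnosis(self, code: str, age_days: int) -> Optional[DiagnosisCodeEntry]:
        """Resolve a bare claims-side code (no system flag), ICD-10 before ICD-9."""
        if age_days < 0:
            raise ValueError(f"age_days must be >= 0, got {age_days}")
        norm = normalize_code(code)
        for system in DIAGNOSIS_SYSTEMS:
            entry = self._diag.get((norm, system))
            if entry is not None and entry.in_age_window(age_days):
                return entry
        return None

    # -- procedures --------------------------------------------------------

    def classify_procedure(self, code: str, code_system: str) -> Optional[str]:
        entry = self._proc.get((normalize_code(code), code_system))
        return None if entry is None else entry.category

    def lookup_procedure(self, code: str) -> Optional[str]:
        """Category of a bare procedure code (CPT before HCPCS), or None."""
        norm = normalize_code(code)
        for system in PROCEDURE_SYSTEMS:
            entry = self._proc.get((norm, system))
            if entry is not None:
                return entry.category
        return None

    # -- revenue -----------------------------------------------------------

    def revenue_unit(self, code: str) -> Optional[str]:
        entry = self._rev.get(normalize_code(code))
        return None if entry is None else entry.unit

    def __len__(self) -> int:
        return (len(self.diagnosis_entries) + len(self.procedure_entries)
                + len(self.revenue_entries))


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "t", "yes", "y"}


def _parse_age(value: str, default: Optional[int]) -> Optional[int]:
    text = str(value).strip()
    if text == "" or text.lower() in {"nan", "none", "inf"}:
        return default
    number = float(text)
    if math.isinf(number):
        return default
    return int(number)


def load_catalog(path: str | Path, strict: bool = True) -> CodeCatalog:
    """Load and validate a catalog file (CSV or TSV, delimiter autodetected).

    In strict mode any invariant violation raises; in lenient mode offending
    rows are dropped with a logged warning carrying the 1-based data row
    number (first occurrence wins for duplicates).
    """
    try:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str,
                            keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot read catalog file {path}: {exc}") from exc
    missing = set(CATALOG_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"catalog file {path} missing columns: {sorted(missing)}")

    diag: list[DiagnosisCodeEntry] = []
    proc: list[ProcedureCodeEntry] = []
    rev: list[RevenueCodeEntry] = []
    seen: set[tuple] = set()

    def problem(row_no: int, message: str) -> None:
        if strict:
            raise CatalogValidationError(f"row {row_no}: {message}")
        logger.warning("catalog row %d dropped: %s", row_no, message)

    for i, row in enumerate(table.to_dict("records"), start=1):
        kind = str(row["kind"]).strip().lower()
        code = normalize_code(row["code"])
        system = str(row["code_system"]).strip().upper()
        if not code:
            problem(i, "empty code")
            continue
        try:
            if kind == "diagnosis":
                entry: object = DiagnosisCodeEntry(
                    code=code,
                    code_system=system,
                    tier=str(row["tier"]).strip().lower(),
                    easy_to_diagnose=_parse_bool(row["easy_to_diagnose"]),
                    clinical_presentation_group=str(
                        row["clinical_presentation_group"]).strip(),
                    organ_system=str(row["organ_system"]).strip(),
                    anomaly_flag=_parse_bool(row["anomaly_flag"]),
                    mca_specific_flag=_parse_bool(row["mca_specific_flag"]),
                    id_flag=_parse_bool(row["id_flag"]),
                    dd_flag=_parse_bool(row["dd_flag"]),
                    e_flag=_parse_bool(row["e_flag"]),
                    age_min_days=_parse_age(row["age_min_days"], 0) or 0,
                    age_max_days=_parse_age(row["age_max_days"], None),
                )
                key = ("diagnosis", code, system)
            elif kind == "procedure":
                entry = ProcedureCodeEntry(
                    code=code, code_system=system,
                    category=str(row["category"]).strip().lower())
                key = ("procedure", code, system)
            elif kind == "revenue":
                entry = RevenueCodeEntry(
                    code=code, unit=str(row["unit"]).strip().upper())
                key = ("revenue", code)
            else:
                problem(i, f"unknown kind {row['kind']!r}")
                continue
            entry.validate()  # type: ignore[union-attr]
        except CatalogValidationError as exc:
            problem(i, str(exc))
            continue
        if key in seen:
            problem(i, f"duplicate code {code} ({system})")
            continue
        seen.add(key)
        if kind == "diagnosis":
            diag.append(entry)  # type: ignore[arg-type]
        elif kind == "procedure":
            proc.append(entry)  # type: ignore[arg-type]
        else:
            rev.append(entry)  # type: ignore[arg-type]

    return CodeCatalog(diag, proc, rev)


def fixture_catalog_path() -> Path:
    """Path of the bundled 40-code fixture catalog."""
    return Path(str(resources.files("claimsphenotyper").joinpath(
        "data/fixture_catalog.csv")))


def load_fixture_catalog() -> CodeCatalog:
    return load_catalog(fixture_catalog_path(), strict=True)
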