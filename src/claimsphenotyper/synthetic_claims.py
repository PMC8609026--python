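"""Synthetic claims generator with planted cohort ground truth.

Real claims extracts from commercial databases are proprietary, so every
pipeline stage here is exercised on synthetic patients whose cohort membership
is planted and recorded in a ground-truth table that the pipeline itself never
reads. The generator emulates the structural features the cohort algorithms
depend on:

* derived dates (integer days since birth, day 0 = birth);
* enrollment eligibility spans, optionally interrupted by coverage gaps so the
  continuous-enrollment filter has a non-trivial kill set;
* claims carrying diagnosis, procedure and revenue codes plus an allowed
  amount and a setting (inpatient / outpatient / pharmacy);
* NICU/PICU room-and-board billing (one revenue-coded claim per unit-day);
* elevated claim rates and costs for labeled patients in the first year after
  their index event, decaying to the background rate, so the 30-day cost
  binning has a planted signal to detect.

Planting contract (checked by the recovery tests):

``conservative``  a possible/probable index diagnosis plus >=1 genetic-test
                  procedure claim later on;
``mca_id_dd_e``   an MCA-specific code, or single-anomaly codes in two organ
                  systems, or an ID/DD/epilepsy code;
``broad_only``    one qualifying code that triggers no other cohort (a plain
                  definite diagnosis, a possible/probable diagnosis with no
                  genetic test, or a lone curated procedure);
``none``          only codes absent from the catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .code_catalog import CodeCatalog, DiagnosisCodeEntry
from .dataset import ClaimsDataset, read_dataset, write_dataset  # noqa: F401
from .errors import ConfigurationError

LABELS = ("none", "broad_only", "mca_id_dd_e", "conservative")
PEDIATRIC_MAX_DAY = 18 * 365  # "<=18 years" on derived-date scale

SEXES = ("M", "F")
RACE_ETHNICITIES = ("white", "hispanic", "black", "asian", "other_unknown")
CENSUS_DIVISIONS = tuple(f"division_{i}" for i in range(1, 10))

# Realistic-looking codes deliberately absent from any catalog (background noise).
NOISE_DIAGNOSIS_CODES = (
    "Z00129", "J069", "K219", "R05", "H669", "L209", "A099", "B349", "M545",
    "N390", "R509", "S0990", "T140", "Z23", "J45909", "R1084", "R112", "K529",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic population.

    Label prevalences default to the published pediatric cohort prevalences
    (Broad 9.4% split into 8.4% broad-only, 0.8% MCA/ID/DD/E, 0.2%
    conservative). ``newborn_fraction`` is the fraction of labeled patients
    planted as critically-ill newborns (index <=28 days plus a NICU stay).
    Costs are log-normal per claim with per-setting parameters; labeled
    patients' post-index claim rate and costs are scaled by
    ``enrichment_multiplier`` at month 0, decaying linearly to 1 by month 12.
    """

    n_patients: int = 10_000
    seed: int = 0
    prevalence_broad_only: float = 0.084
    prevalence_mca_id_dd_e: float = 0.008
    prevalence_conservative: float = 0.002
    newborn_fraction: float = 0.25
    gap_probability: float = 0.15
    mean_gap_days: float = 90.0
    claims_per_month: float = 0.8
    inpatient_fraction: float = 0.08
    pharmacy_fraction: float = 0.25
    cost_log_mean: dict = field(default_factory=lambda: {
        "inpatient": 7.5, "outpatient": 5.0, "pharmacy": 4.0})
    cost_log_sd: dict = field(default_factory=lambda: {
        "inpatient": 1.0, "outpatient": 1.0, "pharmacy": 0.8})
    enrichment_multiplier: float = 4.0
    nicu_los_log_mean: float = 3.0   # exp(3.0) ~ 20 billed NICU days
    nicu_los_log_sd: float = 0.6
    picu_rate_labeled: float = 0.15
    control_nicu_rate: float = 0.0   # >0 breaks the unlabeled-patient contract
    genetic_test_delay_mean: float = 150.0
    definite_transition_rate: float = 0.3

    def validate(self) -> None:
        prevalences = (self.prevalence_broad_only, self.prevalence_mca_id_dd_e,
                       self.prevalence_conservative)
        if any(p < 0 for p in prevalences) or sum(prevalences) > 1:
            raise ConfigurationError(
                f"label prevalences must be >=0 and sum <=1, got {prevalences}")
        for name in ("newborn_fraction", "gap_probability", "picu_rate_labeled",
                     "control_nicu_rate", "definite_transition_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("claims_per_month", "mean_gap_days", "enrichment_multiplier",
                     "genetic_test_delay_mean"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")


@dataclass
class _PlantingPools:
    """Catalog entries eligible for each planting role (wide age window only)."""

    plain_possible_probable: list[DiagnosisCodeEntry]
    plain_definite: list[DiagnosisCodeEntry]
    mca_specific: list[DiagnosisCodeEntry]
    anomaly_by_system: dict[str, list[DiagnosisCodeEntry]]
    id_dd_e: list[DiagnosisCodeEntry]
    genetic_tests: list[str]
    other_workup: list[str]
    nicu_codes: list[str]
    picu_codes: list[str]


def _wide_window(entry: DiagnosisCodeEntry) -> bool:
    return entry.age_min_days == 0 and (
        entry.age_max_days is None or entry.age_max_days >= PEDIATRIC_MAX_DAY)


def _has_flags(entry: DiagnosisCodeEntry) -> bool:
    return (entry.anomaly_flag or entry.mca_specific_flag or entry.id_flag
            or entry.dd_flag or entry.e_flag)


def _build_pools(catalog: CodeCatalog) -> _PlantingPools:
    plain_pp, plain_def, mca_spec, idde = [], [], [], []
    anomaly_by_system: dict[str, list[DiagnosisCodeEntry]] = {}
    for e in catalog.diagnosis_entries:
        if e.easy_to_diagnose or not _wide_window(e):
            continue
        if e.mca_specific_flag:
            mca_spec.append(e)
        elif e.anomaly_flag:
            anomaly_by_system.setdefault(e.organ_system, []).append(e)
        elif e.id_flag or e.dd_flag or e.e_flag:
            idde.append(e)
        elif e.tier in ("possible", "probable"):
            plain_pp.append(e)
        elif e.tier == "definite":
            plain_def.append(e)
    genetic = [p.code for p in catalog.procedure_entries if p.category == "genetic_test"]
    workup = [p.code for p in catalog.procedure_entries if p.category == "other_workup"]
    nicu = [r.code for r in catalog.revenue_entries if r.unit == "NICU"]
    picu = [r.code for r in catalog.revenue_entries if r.unit == "PICU"]
    return _PlantingPools(plain_pp, plain_def, mca_spec, anomaly_by_system, idde,
                          genetic, workup, nicu, picu)


def _check_pools(pools: _PlantingPools, config: GeneratorConfig) -> None:
    any_labeled = (config.prevalence_broad_only + config.prevalence_mca_id_dd_e
                   + config.prevalence_conservative) > 0
    if not any_labeled:
        return
    requirements = {
        "non-easy wide-window possible/probable diagnosis codes":
            pools.plain_possible_probable,
        "non-easy wide-window flag-free definite diagnosis codes":
            pools.plain_definite,
        "genetic_test procedure codes": pools.genetic_tests,
        "other_workup procedure codes": pools.other_workup,
    }
    if config.prevalence_mca_id_dd_e > 0:
        requirements["MCA-specific diagnosis codes"] = pools.mca_specific
        requirements["ID/DD/epilepsy diagnosis codes"] = pools.id_dd_e
    if config.newborn_fraction > 0 or config.control_nicu_rate > 0:
        requirements["NICU revenue codes"] = pools.nicu_codes
    if config.picu_rate_labeled > 0:
        requirements["PICU revenue codes"] = pools.picu_codes
    for kind, pool in requirements.items():
        if not pool:
            raise ConfigurationError(f"catalog lacks {kind} needed for planting")
    if config.prevalence_mca_id_dd_e > 0 and len(pools.anomaly_by_system) < 2:
        raise ConfigurationError(
            "catalog lacks anomaly codes in >=2 distinct organ systems "
            "needed for MCA planting")


class _ClaimSink:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, pid: str, day: int, diagnoses: list[str], procedures: list[str],
            revenues: list[str], amount: float, setting: str) -> None:
        self.rows.append((pid, int(day), diagnoses, procedures, revenues,
                          round(float(amount), 2), setting))


def _lognormal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    return float(np.exp(rng.normal(mu, sigma)))


def generate_population(config: GeneratorConfig,
                        catalog: CodeCatalog) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a synthetic population; returns (dataset, ground-truth table).

    The ground-truth table (patient_id, ground_truth_label, planted_newborn,
    planted_index_day) is for validation only and is never an input to any
    pipeline stage. Fully reproducible for a fixed ``config.seed``.
    """
    config.validate()
    pools = _build_pools(catalog)
    _check_pools(pools, config)
    rng = np.random.default_rng(config.seed)

    p_labeled = [config.prevalence_broad_only, config.prevalence_mca_id_dd_e,
                 config.prevalence_conservative]
    probs = np.array([1 - sum(p_labeled)] + p_labeled)

    patient_rows, span_rows, truth_rows = [], [], []
    sink = _ClaimSink()

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        label = LABELS[int(rng.choice(4, p=probs))]
        sex = SEXES[int(rng.choice(2, p=[0.51, 0.49]))]
        race = RACE_ETHNICITIES[int(rng.choice(5, p=[0.62, 0.12, 0.08, 0.05, 0.13]))]
        division = CENSUS_DIVISIONS[int(rng.integers(0, 9))]
        birth_year = 2007 + int(rng.integers(0, 11))
        children = int(rng.choice([1, 2, 3, 4, 5], p=[0.35, 0.35, 0.18, 0.08, 0.04]))
        patient_rows.append((pid, sex, race, division, birth_year, children))

        newborn = label != "none" and rng.random() < config.newborn_fraction
        if newborn or rng.random() < 0.3:
            start = 0
        else:
            start = int(rng.integers(1, 3650))
        end = start + int(rng.integers(900, 2400))

        index_day: Optional[int] = None
        if label != "none":
            if newborn:
                index_day = int(rng.integers(0, 29))
            else:
                index_day = int(rng.integers(start + 180, end - 420))
            _plant_label(rng, sink, pools, config, pid, label, index_day, end)
            if newborn:
                _plant_nicu_stay(rng, sink, pools, config, pid)
            if rng.random() < config.picu_rate_labeled:
                picu_start = min(index_day + int(rng.integers(0, 60)), end - 3)
                for day in range(picu_start, picu_start + int(rng.integers(1, 6))):
                    sink.add(pid, day, [str(rng.choice(NOISE_DIAGNOSIS_CODES))], [],
                             [str(rng.choice(pools.picu_codes))],
                             _lognormal(rng, config.cost_log_mean["inpatient"],
                                        config.cost_log_sd["inpatient"]),
                             "inpatient")
        elif config.control_nicu_rate > 0 and start == 0 \
                and rng.random() < config.control_nicu_rate:
            los = max(1, int(round(_lognormal(rng, 2.2, 0.5))))
            for day in range(0, los):
                sink.add(pid, day, [str(rng.choice(NOISE_DIAGNOSIS_CODES))], [],
                         [str(rng.choice(pools.nicu_codes))],
                         _lognormal(rng, config.cost_log_mean["inpatient"],
                                    config.cost_log_sd["inpatient"]),
                         "inpatient")

        # enrollment spans, optionally split by one coverage gap
        spans = [(start, end)]
        if rng.random() < config.gap_probability and end - start > 60:
            gap_len = 1 + int(rng.geometric(1.0 / config.mean_gap_days))
            g0 = int(rng.integers(start + 1, end))
            spans = [(start, g0 - 1)]
            if g0 + gap_len <= end:
                spans.append((g0 + gap_len, end))
        for s, e in spans:
            span_rows.append((pid, s, e))

        _background_claims(rng, sink, config, pid, spans)
        if label != "none" and config.enrichment_multiplier > 1:
            _enrichment_claims(rng, sink, config, pid, index_day, end)

        truth_rows.append((pid, label, newborn,
                           -1 if index_day is None else index_day))

    patients = pd.DataFrame(patient_rows, columns=[
        "patient_id", "sex", "race_ethnicity", "census_division",
        "birth_year", "household_children"])
    enrollment = pd.DataFrame(span_rows,
                              columns=["patient_id", "start_day", "end_day"])
    claims = pd.DataFrame(sink.rows, columns=[
        "patient_id", "service_day", "diagnosis_codes", "procedure_codes",
        "revenue_codes", "allowed_amount", "setting"])
    claims = claims.sort_values(["patient_id", "service_day"],
                                kind="stable").reset_index(drop=True)
    ground_truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "ground_truth_label", "planted_newborn", "planted_index_day"])
    dataset = ClaimsDataset(patients, enrollment, claims)
    if config.n_patients:
        dataset.validate()
    return dataset, ground_truth


def _plant_label(rng: np.random.Generator, sink: _ClaimSink, pools: _PlantingPools,
                 config: GeneratorConfig, pid: str, label: str,
                 index_day: int, end: int) -> None:
    """Emit the claims that make ``pid`` satisfy exactly its labeled cohort.

    Planted claims are emitted at their planned days even when a coverage gap
    overlaps them (claims can be adjudicated outside eligibility), so any
    failure to recover a planted label is attributable to the
    continuous-enrollment filter alone.
    """
    amount = _lognormal(rng, config.cost_log_mean["outpatient"],
                        config.cost_log_sd["outpatient"])
    noise = str(rng.choice(NOISE_DIAGNOSIS_CODES))
    plant_definite_followup = False

    if label == "conservative":
        entry = pools.plain_possible_probable[
            int(rng.integers(len(pools.plain_possible_probable)))]
        sink.add(pid, index_day, [entry.code], [], [], amount, "outpatient")
        delay = 1 + min(int(rng.geometric(1.0 / config.genetic_test_delay_mean)),
                        max(end - index_day - 1, 0))
        sink.add(pid, index_day + delay, [noise],
                 [str(rng.choice(pools.genetic_tests))], [],
                 _lognormal(rng, config.cost_log_mean["outpatient"],
                            config.cost_log_sd["outpatient"]),
                 "outpatient")
        plant_definite_followup = rng.random() < config.definite_transition_rate
    elif label == "mca_id_dd_e":
        variant = rng.random()
        if variant < 0.5 and pools.mca_specific:
            entry = pools.mca_specific[int(rng.integers(len(pools.mca_specific)))]
            sink.add(pid, index_day, [entry.code], [], [], amount, "outpatient")
        elif variant < 0.8 and len(pools.anomaly_by_system) >= 2:
            systems = list(pools.anomaly_by_system)
            chosen = rng.choice(len(systems), size=2, replace=False)
            codes = [pools.anomaly_by_system[systems[int(k)]][
                int(rng.integers(len(pools.anomaly_by_system[systems[int(k)]])))].code
                for k in chosen]
            sink.add(pid, index_day, codes, [], [], amount, "outpatient")
        else:
            entry = pools.id_dd_e[int(rng.integers(len(pools.id_dd_e)))]
            sink.add(pid, index_day, [entry.code], [], [], amount, "outpatient")
        plant_definite_followup = rng.random() < config.definite_transition_rate
    elif label == "broad_only":
        variant = rng.random()
        if variant < 0.30:
            entry = pools.plain_definite[int(rng.integers(len(pools.plain_definite)))]
            sink.add(pid, index_day, [entry.code], [], [], amount, "outpatient")
        elif variant < 0.70:
            entry = pools.plain_possible_probable[
                int(rng.integers(len(pools.plain_possible_probable)))]
            sink.add(pid, index_day, [entry.code], [], [], amount, "outpatient")
        elif variant < 0.85:
            sink.add(pid, index_day, [noise],
                     [str(rng.choice(pools.other_workup))], [], amount, "outpatient")
        else:
            sink.add(pid, index_day, [noise],
                     [str(rng.choice(pools.genetic_tests))], [], amount, "outpatient")
    else:  # pragma: no cover - guarded by caller
        raise ValueError(label)

    if plant_definite_followup and index_day + 60 < end:
        day = index_day + int(rng.integers(60, min(360, end - index_day)))
        entry = pools.plain_definite[int(rng.integers(len(pools.plain_definite)))]
        sink.add(pid, day, [entry.code], [], [],
                 _lognormal(rng, config.cost_log_mean["outpatient"],
                            config.cost_log_sd["outpatient"]),
                 "outpatient")


def _plant_nicu_stay(rng: np.random.Generator, sink: _ClaimSink,
                     pools: _PlantingPools, config: GeneratorConfig,
                     pid: str) -> None:
    los = max(1, int(round(_lognormal(rng, config.nicu_los_log_mean,
                                      config.nicu_los_log_sd))))
    code = str(rng.choice(pools.nicu_codes))
    for day in range(0, los):
        sink.add(pid, day, [str(rng.choice(NOISE_DIAGNOSIS_CODES))], [], [code],
                 _lognormal(rng, config.cost_log_mean["inpatient"],
                            config.cost_log_sd["inpatient"]),
                 "inpatient")


def _background_claims(rng: np.random.Generator, sink: _ClaimSink,
                       config: GeneratorConfig, pid: str,
                       spans: list[tuple[int, int]]) -> None:
    settings = ("inpatient", "pharmacy", "outpatient")
    p = [config.inpatient_fraction, config.pharmacy_fraction,
         1 - config.inpatient_fraction - config.pharmacy_fraction]
    for s, e in spans:
        n = int(rng.poisson(config.claims_per_month * (e - s + 1) / 30.0))
        if n == 0:
            continue
        days = rng.integers(s, e + 1, size=n)
        kinds = rng.choice(3, size=n, p=p)
        for day, kind in zip(days, kinds):
            setting = settings[int(kind)]
            sink.add(pid, int(day), [str(rng.choice(NOISE_DIAGNOSIS_CODES))], [], [],
                     _lognormal(rng, config.cost_log_mean[setting],
                                config.cost_log_sd[setting]),
                     setting)


def _enrichment_claims(rng: np.random.Generator, sink: _ClaimSink,
                       config: GeneratorConfig, pid: str, index_day: int,
                       end: int) -> None:
    """Extra post-index utilization for labeled patients, decaying over 12 months."""
    for month in range(12):
        scale = 1 + (config.enrichment_multiplier - 1) * (1 - month / 12.0)
        extra = int(rng.poisson(config.claims_per_month * (scale - 1)))
        for _ in range(extra):
            day = index_day + 30 * month + int(rng.integers(0, 30))
            if day > end:
                continue
            setting = "inpatient" if rng.random() < 2 * config.inpatient_fraction \
                else "outpatient"
            amount = _lognormal(rng, config.cost_log_mean[setting],
                                config.cost_log_sd[setting]) * scale
            sink.add(pid, day, [str(rng.choice(NOISE_DIAGNOSIS_CODES))], [], [],
                     amount, setting)
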