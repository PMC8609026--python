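"""Outcome measures per cohort: testing, ICU use, transitions, costs.

All operations take a *cohort index frame* (patient_id, index_day,
index_category — see :func:`claimsphenotyper.cohort_builder.cohort_index_frame`)
plus the claims dataset and catalog, and compute:

* genetic-test utilization: fraction with >=1 genetic test on/after index,
  number of tests (distinct claim-day x code) and days to first test among
  tested;
* NICU/PICU utilization and NICU length of stay (billed unit-days, contiguous
  runs split at gaps >1 day, totalled per patient) among patients with a stay;
* diagnostic transitions from the index category to a more specific
  first-listed (primary) diagnosis during follow-up, with the full cohort as
  denominator;
* cost accrual in 30-day bins from the index date, per setting, averaged over
  patients enrolled for the entire bin;
* demographic case/control comparison with Welch's two-sided t test
  (proportions compared via the same t on 0/1 indicators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .code_catalog import TIER_RANK, CodeCatalog
from .dataset import ClaimsDataset

TRANSITION_ROWS = (("possible", "probable"), ("possible", "definite"),
                   ("probable", "definite"), ("genetic_test", "definite"),
                   ("other_cpt_hcpcs", "definite"))


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def _five_number(values: list[float]) -> dict:
    if not values:
        return {"mean": float("nan"), "sd": float("nan"), "median": float("nan"),
                "min": float("nan"), "max": float("nan")}
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "median": float(np.median(arr)),
            "min": float(arr.min()), "max": float(arr.max())}


@dataclass
class UtilizationSummary:
    n: int
    fraction_with_genetic_test_pct: float
    tests_per_tested: dict = field(default_factory=dict)   # mean/sd/median/min/max
    mean_days_to_first_test: float = float("nan")
    fraction_with_nicu_stay_pct: float = float("nan")
    fraction_with_picu_stay_pct: float = float("nan")
    nicu_days_among_stayers: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"n": self.n,
               "fraction_with_genetic_test_pct": self.fraction_with_genetic_test_pct,
               "mean_days_to_first_test": self.mean_days_to_first_test,
               "fraction_with_nicu_stay_pct": self.fraction_with_nicu_stay_pct,
               "fraction_with_picu_stay_pct": self.fraction_with_picu_stay_pct}
        out.update({f"n_tests_{k}": v for k, v in self.tests_per_tested.items()})
        out.update({f"nicu_days_{k}": v for k, v in self.nicu_days_among_stayers.items()})
        return out


def _claims_by_patient(dataset: ClaimsDataset) -> dict:
    return {str(pid): group for pid, group
            in dataset.claims.groupby("patient_id", sort=False)}


def genetic_test_utilization(cohort: pd.DataFrame, dataset: ClaimsDataset,
                             catalog: CodeCatalog) -> UtilizationSummary:
    """Genetic-test utilization on/after each patient's index date.

    A test is a (service_day, code) occurrence of a catalog genetic-test
    procedure code; repeats of the same code on the same day count once.
    Count and days-to-first summaries are among tested patients only.
    """
    claims_map = _claims_by_patient(dataset)
    counts, first_days = [], []
    for pid, index_day in zip(cohort["patient_id"].astype(str),
                              cohort["index_day"].astype(int)):
        claims = claims_map.get(pid)
        if claims is None:
            continue
        tests = set()
        for day, codes in zip(claims["service_day"], claims["procedure_codes"]):
            if day < index_day:
                continue
            for code in codes:
                if catalog.lookup_procedure(code) == "genetic_test":
                    tests.add((int(day), code))
        if tests:
            counts.append(len(tests))
            first_days.append(min(day for day, _ in tests) - index_day)
    n = len(cohort)
    fraction = 100.0 * len(counts) / n if n else float("nan")
    return UtilizationSummary(
        n=n,
        fraction_with_genetic_test_pct=fraction,
        tests_per_tested=_five_number(counts),
        mean_days_to_first_test=(float(np.mean(first_days)) if first_days
                                 else float("nan")),
    )


def nicu_stays(patient_claims: pd.DataFrame, catalog: CodeCatalog,
               spans: list[tuple[int, int]],
               gap_threshold: int = 1) -> list[int]:
    """Lengths of NICU stays: distinct billed NICU days within the observation
    period, split into contiguous runs wherever the day gap exceeds
    ``gap_threshold``."""
    days = set()
    for day, revenues in zip(patient_claims["service_day"],
                             patient_claims["revenue_codes"]):
        if any(catalog.revenue_unit(code) == "NICU" for code in revenues):
            if any(s <= day <= e for s, e in spans):
                days.add(int(day))
    if not days:
        return []
    ordered = sorted(days)
    lengths, run = [], 1
    for prev, cur in zip(ordered, ordered[1:]):
        if cur - prev > gap_threshold:
            lengths.append(run)
            run = 1
        else:
            run += 1
    lengths.append(run)
    return lengths


def icu_utilization(cohort: pd.DataFrame, dataset: ClaimsDataset,
                    catalog: CodeCatalog, gap_threshold: int = 1) -> dict:
    """NICU/PICU stay fractions and NICU LOS statistics among stayers.

    A stay is >=1 claim with the unit's revenue code during enrollment; a
    patient's LOS is their total billed NICU days across runs.
    """
    claims_map = _claims_by_patient(dataset)
    spans_map = dataset.spans_by_patient()
    n_nicu = n_picu = 0
    total_days = []
    for pid in cohort["patient_id"].astype(str):
        claims = claims_map.get(pid)
        spans = spans_map.get(pid, [])
        if claims is None:
            continue
        stays = nicu_stays(claims, catalog, spans, gap_threshold)
        if stays:
            n_nicu += 1
            total_days.append(sum(stays))
        picu = any(
            any(catalog.revenue_unit(code) == "PICU" for code in revenues)
            and any(s <= day <= e for s, e in spans)
            for day, revenues in zip(claims["service_day"], claims["revenue_codes"]))
        if picu:
            n_picu += 1
    n = len(cohort)
    return {"n": n,
            "fraction_with_nicu_stay_pct": 100.0 * n_nicu / n if n else float("nan"),
            "fraction_with_picu_stay_pct": 100.0 * n_picu / n if n else float("nan"),
            "nicu_days_among_stayers": _five_number(total_days)}


def utilization_summary(cohort: pd.DataFrame, dataset: ClaimsDataset,
                        catalog: CodeCatalog) -> UtilizationSummary:
    """Combined genetic-test + ICU utilization (one row of the utilization table)."""
    summary = genetic_test_utilization(cohort, dataset, catalog)
    icu = icu_utilization(cohort, dataset, catalog)
    summary.fraction_with_nicu_stay_pct = icu["fraction_with_nicu_stay_pct"]
    summary.fraction_with_picu_stay_pct = icu["fraction_with_picu_stay_pct"]
    summary.nicu_days_among_stayers = icu["nicu_days_among_stayers"]
    return summary


@dataclass
class TransitionSummary:
    n: int
    fractions_pct: dict  # (from, to) -> percent of the full cohort

    @property
    def combined_possible_probable_to_definite_pct(self) -> float:
        return (self.fractions_pct[("possible", "definite")]
                + self.fractions_pct[("probable", "definite")])

    def to_dict(self) -> dict:
        out = {"n": self.n}
        for (src, dst), value in self.fractions_pct.items():
            out[f"{src}_to_{dst}_pct"] = value
        out["combined_possible_probable_to_definite_pct"] = \
            self.combined_possible_probable_to_definite_pct
        return out


def diagnostic_transitions(cohort: pd.DataFrame, dataset: ClaimsDataset,
                           catalog: CodeCatalog) -> TransitionSummary:
    """Fractions transitioning from the index category to a more specific
    primary diagnosis during follow-up.

    A patient counts toward X->Y iff their index category is X and some
    post-index claim's first-listed diagnosis code classifies (at that day's
    age) as Y with Y more specific than X (possible < probable < definite).
    Denominators are the full cohort; a patient can count toward several rows.
    """
    claims_map = _claims_by_patient(dataset)
    counts = {row: 0 for row in TRANSITION_ROWS}
    for pid, index_day, index_category in zip(
            cohort["patient_id"].astype(str), cohort["index_day"].astype(int),
            cohort["index_category"]):
        claims = claims_map.get(pid)
        if claims is None:
            continue
        reached = set()
        for day, codes in zip(claims["service_day"], claims["diagnosis_codes"]):
            if day <= index_day or not codes:
                continue
            entry = catalog.lookup_diagnosis(codes[0], int(day))
            if entry is not None:
                reached.add(entry.tier)
        for src, dst in TRANSITION_ROWS:
            if index_category != src or dst not in reached:
                continue
            if src in TIER_RANK and TIER_RANK[dst] <= TIER_RANK[src]:
                continue
            counts[(src, dst)] += 1
    n = len(cohort)
    fractions = {row: (100.0 * k / n if n else float("nan"))
                 for row, k in counts.items()}
    return TransitionSummary(n=n, fractions_pct=fractions)


@dataclass
class CostBinSeries:
    """Mean allowed cost per fully-enrolled patient in 30-day bins from index."""

    table: pd.DataFrame  # bin, n_contributing, total_mean, inpatient_mean, outpatient_mean


def cost_accrual_30d(cohort: pd.DataFrame, dataset: ClaimsDataset,
                     n_bins: int = 24) -> CostBinSeries:
    """Bin k covers derived days [index+30k, index+30(k+1)); a patient enters
    bin k's denominator iff one enrollment span covers the whole bin.
    Pharmacy claims contribute to the total series only."""
    claims_map = _claims_by_patient(dataset)
    spans_map = dataset.spans_by_patient()
    n_contrib = np.zeros(n_bins, dtype=int)
    sums = {key: np.zeros(n_bins) for key in ("total", "inpatient", "outpatient")}
    for pid, index_day in zip(cohort["patient_id"].astype(str),
                              cohort["index_day"].astype(int)):
        spans = spans_map.get(pid, [])
        contributes = np.zeros(n_bins, dtype=bool)
        for k in range(n_bins):
            lo, hi = index_day + 30 * k, index_day + 30 * (k + 1) - 1
            if any(s <= lo and hi <= e for s, e in spans):
                contributes[k] = True
        n_contrib += contributes
        claims = claims_map.get(pid)
        if claims is None:
            continue
        for day, amount, setting in zip(claims["service_day"],
                                        claims["allowed_amount"],
                                        claims["setting"]):
            k = (int(day) - index_day) // 30
            if k < 0 or k >= n_bins or not contributes[k]:
                continue
            sums["total"][k] += amount
            if setting in ("inpatient", "outpatient"):
                sums[setting][k] += amount
    with np.errstate(invalid="ignore", divide="ignore"):
        means = {key: np.where(n_contrib > 0, val / np.maximum(n_contrib, 1),
                               np.nan)
                 for key, val in sums.items()}
    table = pd.DataFrame({"bin": np.arange(n_bins), "n_contributing": n_contrib,
                          "total_mean": means["total"],
                          "inpatient_mean": means["inpatient"],
                          "outpatient_mean": means["outpatient"]})
    return CostBinSeries(table)


def compare_demographics(cases: pd.DataFrame, controls: pd.DataFrame,
                         continuous: tuple = ("age_years",),
                         binary: dict = None) -> pd.DataFrame:
    """Welch two-sided t test per variable; proportions via the same t on 0/1
    indicators. ``binary`` maps a new variable name to (column, level), e.g.
    {"male": ("sex", "M")}."""
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("compare_demographics requires >=2 units per group")
    binary = binary or {}
    rows = []
    variables = [(name, cases[name].astype(float), controls[name].astype(float))
                 for name in continuous]
    for name, (column, level) in binary.items():
        variables.append((name,
                          (cases[column] == level).astype(float),
                          (controls[column] == level).astype(float)))
    for name, a, b in variables:
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t_stat, p_value = (0.0, float("nan")) if a.mean() == b.mean() \
                else (float("nan"), float("nan"))
        else:
            t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": name,
                     "case_mean": float(a.mean()), "case_sd": float(a.std(ddof=1)),
                     "control_mean": float(b.mean()),
                     "control_sd": float(b.std(ddof=1)),
                     "t": float(t_stat), "p": float(p_value)})
    return pd.DataFrame(rows)
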