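import math

import numpy as np
import pandas as pd
import pytest

from claimsphenotyper import outcomes
from claimsphenotyper.outcomes import (compare_demographics, cost_accrual_30d,
                                       diagnostic_transitions,
                                       genetic_test_utilization, icu_utilization,
                                       nicu_stays, round_half_away)

from conftest import make_dataset
from oracles import (oracle_cost_bins, oracle_genetic_tests,
                     oracle_nicu_total_days, oracle_transitions)


def index_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "index_day", "index_category"])


class TestGeneticTestUtilization:
    def test_counts_and_days_to_first(self, catalog):
        ds = make_dataset(
            [("p1", 0, 2000), ("p2", 0, 2000)],
            [("p1", 100, ["NOISE"], ["81220"], []),
             ("p1", 150, ["NOISE"], ["81415"], []),
             ("p1", 150, ["NOISE"], ["81415"], []),   # same day+code counts once
             ("p2", 500, ["NOISE"], [], [])])
        cohort = index_frame([("p1", 0, "possible"), ("p2", 0, "possible")])
        summary = genetic_test_utilization(cohort, ds, catalog)
        assert summary.fraction_with_genetic_test_pct == 50.0
        assert summary.tests_per_tested["mean"] == 2
        assert summary.mean_days_to_first_test == 100

    def test_tests_before_index_ignored(self, catalog):
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 10, ["NOISE"], ["81220"], [])])
        cohort = index_frame([("p1", 50, "possible")])
        summary = genetic_test_utilization(cohort, ds, catalog)
        assert summary.fraction_with_genetic_test_pct == 0.0


class TestNicuLos:
    def test_contiguous_run_counts_distinct_days(self, catalog):
        claims = [("p1", d, ["NOISE"], [], ["0173"]) for d in range(0, 13)]
        ds = make_dataset([("p1", 0, 2000)], claims)
        stays = nicu_stays(ds.claims, catalog, [(0, 2000)])
        assert stays == [13]

    def test_gap_splits_runs_and_totals(self, catalog):
        days = list(range(0, 6)) + list(range(40, 43))
        claims = [("p1", d, ["NOISE"], [], ["0174"]) for d in days]
        ds = make_dataset([("p1", 0, 2000)], claims)
        stays = nicu_stays(ds.claims, catalog, [(0, 2000)])
        assert stays == [6, 3]
        summary = icu_utilization(index_frame([("p1", 0, "possible")]), ds, catalog)
        assert summary["nicu_days_among_stayers"]["mean"] == 9

    def test_days_outside_enrollment_not_counted(self, catalog):
        claims = [("p1", d, ["NOISE"], [], ["0173"]) for d in (5, 300)]
        ds = make_dataset([("p1", 0, 100)], claims)
        assert nicu_stays(ds.claims, catalog, [(0, 100)]) == [1]

    def test_patient_without_stay_absent_from_los_stats(self, catalog):
        ds = make_dataset([("p1", 0, 500), ("p2", 0, 500)],
                          [("p1", 5, ["NOISE"], [], ["0173"]),
                           ("p2", 5, ["NOISE"], [], [])])
        summary = icu_utilization(index_frame([("p1", 0, "x"), ("p2", 0, "x")]),
                                  ds, catalog)
        assert summary["fraction_with_nicu_stay_pct"] == 50.0
        assert summary["nicu_days_among_stayers"]["min"] == 1


class TestTransitions:
    def test_multi_step_counting_rule(self, catalog):
        # index possible; probable primary at day 30; definite primary at day 60
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 0, ["Q210"], [], []),
                           ("p1", 30, ["Q897", "NOISE"], [], []),
                           ("p1", 60, ["E7521"], [], [])])
        cohort = index_frame([("p1", 0, "possible")])
        summary = diagnostic_transitions(cohort, ds, catalog)
        assert summary.fractions_pct[("possible", "probable")] == 100.0
        assert summary.fractions_pct[("possible", "definite")] == 100.0
        assert summary.fractions_pct[("probable", "definite")] == 0.0

    def test_definite_index_contributes_nothing(self, catalog):
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 0, ["E7521"], [], []),
                           ("p1", 60, ["E700"], [], [])])
        summary = diagnostic_transitions(index_frame([("p1", 0, "definite")]),
                                         ds, catalog)
        assert all(v == 0.0 for v in summary.fractions_pct.values())

    def test_only_primary_code_counts(self, catalog):
        # definite code in second position does not trigger a transition
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 0, ["Q210"], [], []),
                           ("p1", 60, ["NOISE", "E7521"], [], [])])
        summary = diagnostic_transitions(index_frame([("p1", 0, "possible")]),
                                         ds, catalog)
        assert summary.fractions_pct[("possible", "definite")] == 0.0

    def test_combined_equals_sum_of_components(self, catalog):
        ds = make_dataset(
            [("a", 0, 2000), ("b", 0, 2000), ("c", 0, 2000)],
            [("a", 0, ["Q210"], [], []), ("a", 50, ["E7521"], [], []),
             ("b", 0, ["Q897"], [], []), ("b", 50, ["E700"], [], []),
             ("c", 0, ["Q210"], [], [])])
        cohort = index_frame([("a", 0, "possible"), ("b", 0, "probable"),
                              ("c", 0, "possible")])
        summary = diagnostic_transitions(cohort, ds, catalog)
        assert summary.combined_possible_probable_to_definite_pct == \
            pytest.approx(summary.fractions_pct[("possible", "definite")]
                          + summary.fractions_pct[("probable", "definite")])

    def test_genetic_test_index_to_definite(self, catalog):
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 0, ["NOISE"], ["81220"], []),
                           ("p1", 90, ["E7521"], [], [])])
        summary = diagnostic_transitions(index_frame([("p1", 0, "genetic_test")]),
                                         ds, catalog)
        assert summary.fractions_pct[("genetic_test", "definite")] == 100.0


class TestCostAccrual:
    def test_binning_arithmetic(self, catalog):
        ds = make_dataset([("p1", 0, 2000)],
                          [("p1", 135, ["NOISE"], [], [], 100.0, "outpatient")])
        series = cost_accrual_30d(index_frame([("p1", 100, "x")]), ds, n_bins=3)
        assert series.table["total_mean"].tolist() == [0.0, 100.0, 0.0]
        assert series.table["n_contributing"].tolist() == [1, 1, 1]

    def test_partial_bin_enrollment_excluded(self, catalog):
        ds = make_dataset([("p1", 0, 145)],
                          [("p1", 140, ["NOISE"], [], [], 50.0, "outpatient")])
        series = cost_accrual_30d(index_frame([("p1", 100, "x")]), ds, n_bins=2)
        # enrolled through day 145: bin 0 = [100, 129] covered, bin 1 = [130, 159] not
        assert series.table["n_contributing"].tolist() == [1, 0]
        assert series.table["total_mean"][0] == 0.0
        assert math.isnan(series.table["total_mean"][1])

    def test_setting_split_and_pharmacy_in_total_only(self, catalog):
        ds = make_dataset(
            [("p1", 0, 2000)],
            [("p1", 10, ["NOISE"], [], [], 100.0, "inpatient"),
             ("p1", 11, ["NOISE"], [], [], 30.0, "outpatient"),
             ("p1", 12, ["NOISE"], [], [], 7.0, "pharmacy")])
        series = cost_accrual_30d(index_frame([("p1", 0, "x")]), ds, n_bins=1)
        row = series.table.iloc[0]
        assert row["total_mean"] == 137.0
        assert row["inpatient_mean"] == 100.0
        assert row["outpatient_mean"] == 30.0

    def test_no_claims_zero_means_with_full_denominators(self, catalog):
        ds = make_dataset([("p1", 0, 2000)], [("p1", 5, ["NOISE"], [], [])])
        series = cost_accrual_30d(index_frame([("p1", 1000, "x")]), ds, n_bins=4)
        assert series.table["n_contributing"].tolist() == [1, 1, 1, 1]
        assert series.table["total_mean"].tolist() == [0.0] * 4


class TestOracleEquivalence:
    """All outcome operations against brute-force recomputation on random
    small fixtures."""

    def test_outcomes_match_brute_force(self, catalog):
        from test_cohort_builder import random_small_dataset
        rng = np.random.default_rng(99)
        for _ in range(25):
            ds = random_small_dataset(rng, catalog)
            pids = list(ds.patients["patient_id"])
            rows = [(pid, int(rng.integers(0, 800)),
                     ["possible", "probable", "definite", "genetic_test"][
                         int(rng.integers(0, 4))]) for pid in pids]
            cohort = index_frame(rows)
            summary = genetic_test_utilization(cohort, ds, catalog)
            n_tested = expected_total = 0
            for pid, index_day, _ in rows:
                count, first = oracle_genetic_tests(ds, catalog, pid, index_day)
                n_tested += count > 0
                expected_total += count
            assert summary.fraction_with_genetic_test_pct == \
                pytest.approx(100.0 * n_tested / len(rows))
            icu = icu_utilization(cohort, ds, catalog)
            expected_days = [oracle_nicu_total_days(ds, catalog, pid)
                             for pid in pids]
            stayers = [d for d in expected_days if d > 0]
            assert icu["fraction_with_nicu_stay_pct"] == \
                pytest.approx(100.0 * len(stayers) / len(pids))
            if stayers:
                assert icu["nicu_days_among_stayers"]["mean"] == \
                    pytest.approx(np.mean(stayers))
            transitions = diagnostic_transitions(cohort, ds, catalog)
            for key in transitions.fractions_pct:
                expected = sum(key in oracle_transitions(ds, catalog, pid, d, c)
                               for pid, d, c in rows)
                assert transitions.fractions_pct[key] == \
                    pytest.approx(100.0 * expected / len(rows)), key
            series = cost_accrual_30d(cohort, ds, n_bins=5)
            for k in range(5):
                contrib = totals = 0
                for pid, index_day, _ in rows:
                    bins = oracle_cost_bins(ds, pid, index_day, 5)
                    contrib += bins[k][0]
                    totals += bins[k][1]
                assert series.table["n_contributing"][k] == contrib
                if contrib:
                    assert series.table["total_mean"][k] == \
                        pytest.approx(totals / contrib)


class TestDemographicComparison:
    def test_identical_groups_t_zero(self):
        frame = pd.DataFrame({"age_years": [1.0, 2.0, 3.0]})
        result = compare_demographics(frame, frame.copy())
        assert result.iloc[0]["t"] == pytest.approx(0.0)

    def test_shifted_groups_match_closed_form_welch(self):
        # {1,2,3} vs {11,12,13}: t = -10 / sqrt(1/3 + 1/3)
        cases = pd.DataFrame({"age_years": [1.0, 2.0, 3.0]})
        controls = pd.DataFrame({"age_years": [11.0, 12.0, 13.0]})
        result = compare_demographics(cases, controls)
        assert result.iloc[0]["t"] == pytest.approx(-10 / math.sqrt(2 / 3))
        assert result.iloc[0]["p"] < 0.01

    def test_proportions_via_indicator_t(self):
        cases = pd.DataFrame({"sex": ["M", "M", "F", "M"]})
        controls = pd.DataFrame({"sex": ["F", "F", "M", "F"]})
        result = compare_demographics(cases, controls, continuous=(),
                                      binary={"male": ("sex", "M")})
        assert result.iloc[0]["case_mean"] == 0.75
        assert result.iloc[0]["control_mean"] == 0.25

    def test_single_unit_group_is_error(self):
        one = pd.DataFrame({"age_years": [1.0]})
        many = pd.DataFrame({"age_years": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_demographics(one, many)

    def test_degenerate_zero_variance_reported_not_applicable(self):
        a = pd.DataFrame({"age_years": [2.0, 2.0, 2.0]})
        b = pd.DataFrame({"age_years": [5.0, 5.0, 5.0]})
        result = compare_demographics(a, b)
        assert math.isnan(result.iloc[0]["p"])


@pytest.mark.parametrize("value,expected", [
    (1.25, 1.3), (1.24, 1.2), (-1.25, -1.3), (0.05, 0.1), (9.4499, 9.4)])
def test_round_half_away_from_zero(value, expected):
    assert round_half_away(value, 1) == expected
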