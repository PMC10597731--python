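"""Percent-difference statistic, summaries and the Mann-Whitney test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from l3comp.errors import InsufficientDataError, InvalidInputError
from l3comp.variability import (
    avg_percent_difference,
    build_variability_records,
    cohort_summary,
    mann_whitney,
    sex_comparison,
)


def brute_force_mann_whitney(a, b):
    """Independent oracle: enumerate every assignment of the pooled
    values to the two groups and count assignments at least as far from
    the null mean of U as the observed one."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    mu = n_a * (n - n_a) / 2.0

    def u_of(idx):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)

    u_obs = u_of(tuple(range(n_a)))
    count = total = 0
    for idx in itertools.combinations(range(n), n_a):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


class TestAvgPercentDifference:
    @pytest.mark.parametrize(
        "mid,others,expected",
        [
            (200, [180, 220, 200], 20 / 3),
            (-100, [-90], 10.0),  # negative baseline handled by the absolute value
            (100, [100, 100], 0.0),
        ],
    )
    def test_hand_computed_values(self, mid, others, expected):
        assert avg_percent_difference(mid, others) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "mid,others",
        [(0, [1, 2]), (math.nan, [1, 2]), (100, []), (100, [math.nan])],
    )
    def test_undefined_marker_cases(self, mid, others):
        assert math.isnan(avg_percent_difference(mid, others))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        mid=st.floats(0.1, 1e4),
        others=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=12),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariant(self, mid, others, c):
        base = avg_percent_difference(mid, others)
        scaled = avg_percent_difference(c * mid, [c * v for v in others])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        mid=st.floats(0.1, 1e4),
        others=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=12),
    )
    def test_nonnegative_zero_iff_identical(self, mid, others):
        v = avg_percent_difference(mid, others)
        assert v >= 0.0
        assert (v == 0.0) == all(o == mid for o in others)


class TestCohortSummary:
    def test_order_statistics(self):
        assert cohort_summary([1, 2, 3, 4, 5]) == (3.0, (2.0, 4.0))
        assert cohort_summary([7]) == (7.0, (7.0, 7.0))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(13)
        vals = list(rng.normal(size=30))
        assert cohort_summary(vals) == cohort_summary(sorted(vals, reverse=True))

    def test_monte_carlo_matches_analytic_quantiles(self):
        rng = np.random.default_rng(14)
        draws = rng.normal(0.0, 1.0, size=1000)
        med, (q25, q75) = cohort_summary(draws)
        assert med == pytest.approx(0.0, abs=0.15)
        assert q25 == pytest.approx(stats.norm.ppf(0.25), abs=0.15)
        assert q75 == pytest.approx(stats.norm.ppf(0.75), abs=0.15)

    def test_no_defined_values(self):
        with pytest.raises(InsufficientDataError):
            cohort_summary([math.nan])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert r.u == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_complete_ties(self):
        assert mann_whitney([5, 5, 5], [5, 5, 5], mode="exact").p_value == 1.0
        assert mann_whitney([5, 5, 5], [5, 5, 5], mode="asymptotic").p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            mann_whitney([], [1.0])

    def test_exact_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(15)
        for _ in range(120):
            n_a, n_b = rng.integers(1, 7, size=2)
            a = rng.integers(0, 4, size=n_a).astype(float)
            b = rng.integers(0, 4, size=n_b).astype(float)
            u_ref, p_ref = brute_force_mann_whitney(a, b)
            r = mann_whitney(a, b, mode="exact")
            assert r.u == u_ref
            assert r.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(16)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 15, size=2)
            a = rng.integers(0, 6, size=n_a).astype(float)
            b = rng.integers(0, 6, size=n_b).astype(float)
            u_ab = mann_whitney(a, b, mode="asymptotic").u
            u_ba = mann_whitney(b, a, mode="asymptotic").u
            assert u_ab + u_ba == pytest.approx(n_a * n_b)

    def test_asymptotic_close_to_exact_at_n6(self):
        rng = np.random.default_rng(17)
        devs = []
        for _ in range(200):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1.0, size=6)
            pe = mann_whitney(a, b, mode="exact").p_value
            pa = mann_whitney(a, b, mode="asymptotic").p_value
            devs.append(abs(pe - pa))
        assert max(devs) <= 0.03

    def test_auto_mode_selection(self):
        small = mann_whitney([1.0] * 4, [2.0] * 9, mode="auto")
        large = mann_whitney([1.0] * 13, [2.0] * 4, mode="auto")
        assert small.mode_used == "exact"
        assert large.mode_used == "asymptotic"

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(18)
        a = rng.normal(size=7)
        b = rng.normal(0.3, 1.0, size=6)
        mine = mann_whitney(a, b, mode="exact")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert mine.u == ref.statistic
        # distinct two-sided conventions agree for continuous (tie-free) data
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def _truth_frame(n_f=4, n_m=4, seed=19):
    from l3comp.phantom import cohort_truth_measures

    return cohort_truth_measures(n_f, n_m, seed=seed)


class TestRecordsAndSexComparison:
    def test_cohort_records_all_defined(self):
        df = _truth_frame(10, 10)
        records = build_variability_records(df)
        assert len(records) == 20
        assert all(not math.isnan(v) for r in records for v in r.values.values())

    def test_zero_vat_mid_propagates_undefined(self):
        rows = []
        for i, (is_mid, vat_area) in enumerate([(False, 10.0), (True, 0.0), (False, 12.0)]):
            for t, area in (("sm", 50.0), ("vat", vat_area), ("sat", 80.0)):
                rows.append(
                    {
                        "patient_id": "X",
                        "sex": "female",
                        "slice_index": i,
                        "is_mid": is_mid,
                        "tissue": t,
                        "area_cm2": area,
                        "radiodensity_hu": math.nan if (t == "vat" and area == 0) else -90.0,
                    }
                )
        (rec,) = build_variability_records(pd.DataFrame(rows))
        assert math.isnan(rec.values["vat_area"])
        assert math.isnan(rec.values["vat_radiodensity"])
        assert not math.isnan(rec.values["sm_area"])

    def test_two_slice_patient_minimum_case(self):
        rows = [
            {
                "patient_id": "Y",
                "sex": "male",
                "slice_index": i,
                "is_mid": i == 0,
                "tissue": t,
                "area_cm2": 100.0 + 10 * i,
                "radiodensity_hu": 40.0,
            }
            for i in range(2)
            for t in ("sm", "vat", "sat")
        ]
        (rec,) = build_variability_records(pd.DataFrame(rows))
        assert rec.values["sm_area"] == pytest.approx(10.0)

    def test_single_sex_cohort_rejected(self):
        df = _truth_frame(3, 3)
        records = [r for r in build_variability_records(df) if r.sex == "female"]
        with pytest.raises(InsufficientDataError):
            sex_comparison(records)

    def test_summary_schema_and_iqr_ordering(self):
        records = build_variability_records(_truth_frame(8, 8))
        summaries = sex_comparison(records)
        assert len(summaries) == 18  # 6 measures x (all, female, male)
        for s in summaries:
            assert s.iqr_low <= s.median <= s.iqr_high
            assert s.significant == (s.p_value < 0.05)
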