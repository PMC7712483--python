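"""Incidence arithmetic, group summaries, and the rank-sum test (with an
independent enumeration oracle)."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pompe_nbs.diagnosis import DiagnosisLabel
from pompe_nbs.errors import ConsistencyError, DomainError, EmptyGroupError
from pompe_nbs.stats import (cohort_report, group_summary, incidence,
                             rank_sum_test)

TOTAL = 531_139


class TestIncidence:
    @pytest.mark.parametrize("cases,text", [
        (2, "1:265,570"),    # 531139/2 = 265,569.5 rounds half-up
        (31, "1:17,134"),
        (30, "1:17,705"),
        (33, "1:16,095"),
        (63, "1:8,431"),
        (35, "1:15,175"),
        (15, "1:35,409"),
        (TOTAL, "1:1"),
    ])
    def test_reported_pairs(self, cases, text):
        assert incidence(cases, TOTAL).text == text

    def test_zero_cases_undefined(self):
        with pytest.raises(DomainError):
            incidence(0, TOTAL)

    def test_more_cases_than_screened_rejected(self):
        with pytest.raises(DomainError):
            incidence(10, 5)

    @given(cases=st.integers(min_value=1, max_value=10_000),
           total=st.integers(min_value=1, max_value=10_000_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_denominator_within_half_of_ratio(self, cases, total):
        if total < cases:
            total, cases = cases, total
        n = incidence(cases, total).denominator
        assert abs(total / cases - n) <= 0.5


class TestGroupSummary:
    def test_singleton(self):
        s = group_summary([5.0])
        assert (s.n, s.median, s.minimum, s.maximum) == (1, 5.0, 5.0, 5.0)

    def test_missing_values_excluded(self):
        s = group_summary([1.0, None, 3.0, float("nan"), 2.0])
        assert s.n == 3 and s.median == 2.0

    def test_even_n_uses_midpoint_median(self):
        assert group_summary([1, 2, 3, 4]).median == pytest.approx(2.5)

    def test_order_statistics_are_ordered(self):
        rng = np.random.default_rng(7)
        s = group_summary(rng.normal(size=101).tolist())
        assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum

    def test_all_missing_rejected(self):
        with pytest.raises(EmptyGroupError):
            group_summary([None, float("nan")])


def oracle_rank_sum_p(a, b):
    """Independent two-sided exact p: explicit mid-ranks plus enumeration of
    all C(n, n1) group assignments (doubling convention, capped at 1)."""
    pooled = sorted(list(a) + list(b))
    # mid-ranks computed by hand
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and pooled[j] == pooled[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        ranks.setdefault(pooled[i], mid)
        i = j
    pooled_ranks = [ranks[v] for v in sorted(list(a) + list(b))]
    # ranks of the actual first group: consume matching values
    remaining = sorted(list(a) + list(b))
    w_obs = sum(ranks[v] for v in a)
    n, n1 = len(remaining), len(a)
    sums = [sum(pooled_ranks[i] for i in idx)
            for idx in combinations(range(n), n1)]
    le = sum(1 for s in sums if s <= w_obs + 1e-9)
    ge = sum(1 for s in sums if s >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(le, ge) / len(sums))


class TestRankSum:
    def test_separated_groups_exact_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact_enumeration"
        assert res.p_two_sided == pytest.approx(0.10)  # 2 * 1/20

    def test_identical_multisets_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.method == "exact_enumeration"
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyGroupError):
            rank_sum_test([], [1.0])

    def test_missing_values_dropped(self):
        res = rank_sum_test([1, None, 2, 3], [4, 5, float("nan"), 6])
        assert (res.n1, res.n2) == (3, 3)

    @given(data=st.data(),
           n1=st.integers(min_value=1, max_value=6),
           n2=st.integers(min_value=1, max_value=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_matches_enumeration_oracle(self, data, n1, n2):
        values = st.integers(min_value=0, max_value=8)  # ties likely
        a = data.draw(st.lists(values, min_size=n1, max_size=n1))
        b = data.draw(st.lists(values, min_size=n2, max_size=n2))
        res = rank_sum_test(a, b)
        assert res.method == "exact_enumeration"
        assert res.p_two_sided == pytest.approx(oracle_rank_sum_p(a, b), abs=1e-12)

    @staticmethod
    def _forced_normal_p(a, b):
        from pompe_nbs import stats as _stats

        limit = _stats.EXACT_ENUMERATION_LIMIT
        try:
            _stats.EXACT_ENUMERATION_LIMIT = 0
            return rank_sum_test(a, b).p_two_sided
        finally:
            _stats.EXACT_ENUMERATION_LIMIT = limit

    def test_normal_approximation_close_to_exact_at_boundary(self):
        """At n1=n2=6 on continuous (tie-free) data the continuity-corrected
        normal approximation agrees with the exact enumeration to within
        0.03."""
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(30):
            a = rng.normal(0, 1, 6).tolist()
            b = rng.normal(rng.uniform(0, 1.5), 1, 6).tolist()
            exact = rank_sum_test(a, b).p_two_sided
            approx = self._forced_normal_p(a, b)
            worst = max(worst, abs(exact - approx))
        assert worst <= 0.03

    def test_tie_corrected_variance_matches_independent_implementation(self):
        """On heavily tied data the tie-corrected, continuity-corrected
        normal path agrees with an independent implementation."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(13)
        a = rng.integers(0, 5, 25).tolist()
        b = (rng.integers(0, 5, 20) + 1).tolist()
        ours = rank_sum_test(a, b).p_two_sided
        theirs = mannwhitneyu(a, b, alternative="two-sided",
                              use_continuity=True, method="asymptotic").pvalue
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(3)
        res = rank_sum_test(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        assert res.method == "normal_approximation"
        assert res.p_two_sided < 0.05

    def test_agrees_with_scipy_at_scale(self):
        """Cross-check the normal path against an independent implementation."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.4, 1.2, 35)
        ours = rank_sum_test(a, b).p_two_sided
        theirs = mannwhitneyu(a, b, alternative="two-sided",
                              use_continuity=True, method="asymptotic").pvalue
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestCohortReport:
    REPORTED = {
        DiagnosisLabel.IOPD: 2, DiagnosisLabel.LOPD: 31,
        DiagnosisLabel.SUSPECTED_LOPD: 30, DiagnosisLabel.CARRIER: 35,
        DiagnosisLabel.PSEUDODEFICIENCY: 15, DiagnosisLabel.FALSE_POSITIVE: 2,
    }

    def test_reported_cohort_summary(self):
        s = cohort_report(self.REPORTED, TOTAL)
        assert s.total_positive == 115
        assert s.positive_rate_percent == pytest.approx(0.02)
        assert s.incidences["IOPD+LOPD"].text == "1:16,095"
        assert s.incidences["IOPD+LOPD+suspected_LOPD"].text == "1:8,431"

    def test_zero_positives(self):
        s = cohort_report([], TOTAL)
        assert s.total_positive == 0
        assert s.positive_rate_percent == 0.0
        assert s.incidences == {}

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ConsistencyError):
            cohort_report(self.REPORTED, 100)

    def test_markdown_rendering_mentions_totals(self):
        text = cohort_report(self.REPORTED, TOTAL).to_markdown()
        assert "531,139" in text and "115" in text
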