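"""Fisher exact test (vs two independent oracles) and cohort statistics."""

import math
from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from ichthyoscore.cohort import Cohort, DiagnosisGroup
from ichthyoscore.grading import CollapsePolicy, collapse
from ichthyoscore.grammar import Grade
from ichthyoscore.stats import (
    ContingencyTable2x2,
    build_flg_contingency,
    cohort_report,
    count_biopsies,
    fisher_two_sided,
    inflammation_present,
    prevalence,
    reduced_or_absent_sg,
)


def brute_force_fisher(t: ContingencyTable2x2) -> float:
    """Independent oracle: enumerate all margin-preserving tables and sum the
    probabilities of those no more likely than the observed one, computing
    each probability directly from the factorial formula."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    n = t.n
    if 0 in (r1, r2, c1, c2):
        return 1.0

    def prob(a: int) -> Fraction:
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        num = (math.factorial(r1) * math.factorial(r2)
               * math.factorial(c1) * math.factorial(c2))
        den = (math.factorial(n) * math.factorial(a) * math.factorial(b)
               * math.factorial(c) * math.factorial(d))
        return Fraction(num, den)

    p_obs = prob(t.a)
    total = Fraction(0)
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(a) <= p_obs:
            total += prob(a)
    return float(total)


class TestFisher:
    def test_trivial_symmetric_table(self):
        assert fisher_two_sided(ContingencyTable2x2(1, 0, 0, 1)) == 1.0

    def test_zero_margin_convention(self):
        assert fisher_two_sided(ContingencyTable2x2(0, 0, 3, 5)) == 1.0

    def test_exhaustive_oracle_all_tables_up_to_n_twelve(self):
        """Equality with the enumeration oracle for every 2x2 with N <= 12."""
        checked = 0
        for a, b, c, d in product(range(13), repeat=4):
            n = a + b + c + d
            if not 1 <= n <= 12:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_two_sided(t) == pytest.approx(brute_force_fisher(t), abs=1e-12)
            checked += 1
        assert checked == 1819  # all non-empty tables with N <= 12

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(min_value=0, max_value=25)] * 4))
    def test_matches_scipy_and_is_symmetric(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        p = fisher_two_sided(t)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(
            scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-9, abs=1e-12
        )
        # invariances: swap rows, swap columns, transpose
        for t2 in (
            ContingencyTable2x2(c, d, a, b),
            ContingencyTable2x2(b, a, d, c),
            ContingencyTable2x2(a, c, b, d),
        ):
            assert fisher_two_sided(t2) == pytest.approx(p, rel=1e-12)

    def test_negative_or_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestPrevalence:
    def test_iv_inflammation_is_75_percent(self, fixture_cohort):
        r = prevalence(
            fixture_cohort,
            lambda p: p.diagnosis_group is DiagnosisGroup.IV,
            inflammation_present,
        )
        assert (r.numerator, r.denominator) == (6, 8)
        assert r.fraction == pytest.approx(0.75)

    def test_xli_reduced_or_absent_sg_is_6_of_10(self, fixture_cohort):
        r = prevalence(
            fixture_cohort,
            lambda p: p.diagnosis_group is DiagnosisGroup.XLI,
            reduced_or_absent_sg,
        )
        assert (r.numerator, r.denominator) == (6, 10)

    def test_tautological_feature_is_total(self, fixture_cohort):
        r = prevalence(fixture_cohort, lambda p: True, lambda b: True)
        assert (r.numerator, r.denominator) == (66, 66)

    def test_empty_group_is_an_error(self, fixture_cohort):
        with pytest.raises(ValueError, match="no patients"):
            prevalence(fixture_cohort, lambda p: False, lambda b: True)

    def test_numerator_monotone_in_feature_strength(self, fixture_cohort):
        """A weaker predicate can only increase the numerator."""
        group = lambda p: p.diagnosis_group is DiagnosisGroup.ARCI
        strong = prevalence(
            fixture_cohort, group,
            lambda b: collapse(b.inflammation, CollapsePolicy.OPTIMISTIC_MAX) >= Grade.HIGH,
        )
        weak = prevalence(fixture_cohort, group, inflammation_present)
        assert weak.numerator >= strong.numerator


class TestCountBiopsies:
    def test_psd_acanthosis_distribution(self, fixture_cohort):
        """Grade distribution (−, +, ++, +++) over the 18 PSD biopsies."""
        psd = lambda p: p.diagnosis_group is DiagnosisGroup.PSD
        dist = [
            count_biopsies(
                fixture_cohort, psd,
                lambda b, g=g: collapse(b.acanthosis, CollapsePolicy.OPTIMISTIC_MAX) == g,
            )
            for g in (Grade.LOW, Grade.MID, Grade.HIGH, Grade.TOP)
        ]
        assert dist == [1, 6, 9, 2]

    def test_psd_total_biopsies(self, fixture_cohort):
        psd = lambda p: p.diagnosis_group is DiagnosisGroup.PSD
        assert count_biopsies(fixture_cohort, psd, lambda b: True) == 18

    def test_no_matching_patients_counts_zero(self, fixture_cohort):
        assert count_biopsies(fixture_cohort, lambda p: False, lambda b: True) == 0


class TestFlgContingency:
    def test_monoallelic_group_size_is_five(self, fixture_cohort):
        t = build_flg_contingency(fixture_cohort, "prominent_hyperkeratosis")
        assert t.a + t.b == 5
        assert t.c + t.d == 3

    def test_prominent_hyperkeratosis_table(self, fixture_cohort):
        t = build_flg_contingency(fixture_cohort, "prominent_hyperkeratosis")
        assert t.as_rows() == ((0, 5), (2, 1))

    def test_absent_sg_table_reproduces_published_p(self, fixture_cohort):
        """Strict span coding gives mono 3/5 vs biallelic 3/3 absent SG and
        a two-sided exact p of 0.464, matching the published comparison."""
        t = build_flg_contingency(fixture_cohort, "absent_sg")
        assert t.as_rows() == ((3, 2), (3, 0))
        assert fisher_two_sided(t) == pytest.approx(13 / 28)
        assert round(fisher_two_sided(t), 3) == 0.464

    def test_unknown_feature_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="feature"):
            build_flg_contingency(fixture_cohort, "sparkles")

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            build_flg_contingency(Cohort(patients=()), "absent_sg")


class TestCohortReport:
    def test_headline_numbers(self, fixture_cohort):
        rep = cohort_report(fixture_cohort)
        assert rep["iv_inflammation_prevalence"]["percent"] == 75.0
        assert rep["xli_reduced_or_absent_sg"]["numerator"] == 6
        assert rep["genetic_confirmation"]["percent"] == 89.4
        assert rep["flg_contingency"]["absent_sg"]["p_two_sided"] == pytest.approx(13 / 28)
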