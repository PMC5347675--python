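"""PRR, delta-method CI, two-tailed Fisher test, and comparison tables."""

import math
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from prrnet import (
    ContingencyTable,
    Sex,
    compare_drugs,
    count_affected,
    fisher_exact_two_tailed,
    fisher_two_tailed_cells,
    fixture_from_counts,
    build_cohort,
    gender_composition,
    prr,
    prr_ci,
    stars_for,
    top_events,
)
from prrnet.disproportionality import format_prr, round_half_up


def fisher_enumeration(x11, x12, x21, x22):
    """Exact two-tailed Fisher p by enumerating the hypergeometric support.

    Integer arithmetic, so probability ties are resolved exactly.
    """
    r1, r2, c1 = x11 + x12, x21 + x22, x11 + x21
    observed = comb(r1, x11) * comb(r2, c1 - x11)
    total = comb(r1 + r2, c1)
    acc = 0
    for x in range(max(0, c1 - r2), min(c1, r1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= observed:
            acc += w
    return Fraction(acc, total)


class TestCountsAndRanking:
    def test_case_level_dedup_and_empty(self, male_cohorts):
        exposed, _ = male_cohorts
        assert count_affected(exposed, "ERECTILE DYSFUNCTION") == 1046
        empty = build_cohort([], "FINASTERIDE", Sex.MALE)
        assert count_affected(empty, "ANYTHING") == 0

    def test_top_events_tie_break_is_lexicographic(self):
        reports = fixture_from_counts(
            [("B EVENT", 2, 0), ("A EVENT", 2, 0), ("C EVENT", 3, 0)],
            5, 1, "D1", "D2", Sex.MALE,
        )
        cohort = build_cohort(reports, "D1", Sex.MALE)
        ranked = top_events(cohort, 10)
        assert ranked[:3] == [("C EVENT", 3), ("A EVENT", 2), ("B EVENT", 2)]

    def test_top_events_short_cohort_returns_fewer(self):
        reports = fixture_from_counts([("ONLY EVENT", 2, 0)], 2, 1, "D1", "D2", Sex.MALE)
        cohort = build_cohort(reports, "D1", Sex.MALE)
        assert top_events(cohort, 10) == [("ONLY EVENT", 2)]

    def test_top_events_rejects_nonpositive_n(self, male_cohorts):
        with pytest.raises(ValueError):
            top_events(male_cohorts[0], 0)


class TestPrr:
    def test_published_value(self):
        assert round_half_up(prr(ContingencyTable(1046, 2076, 4, 92)), 2) == 11.59

    def test_equal_proportions_give_unity(self):
        assert prr(ContingencyTable(7, 50, 7, 50)) == pytest.approx(1.0)

    def test_zero_sentinel_when_exposed_unaffected(self):
        assert prr(ContingencyTable(0, 60, 8, 99)) == 0.0
        assert format_prr(0.0) == "0.00"

    def test_undefined_when_comparator_unaffected(self):
        assert prr(ContingencyTable(956, 2076, 0, 92)) is None
        assert prr(ContingencyTable(0, 10, 0, 10)) is None
        assert format_prr(None) == "N/A"

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(5, 4, 0, 10)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 1, 10)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(st.integers(1, 200), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 200)))
    def test_reciprocity(self, cells):
        a1, ea, b1, eb = cells
        t = ContingencyTable(a1, a1 + ea, b1, b1 + eb)
        swapped = ContingencyTable(b1, b1 + eb, a1, a1 + ea)
        assert prr(t) * prr(swapped) == pytest.approx(1.0)

    def test_monotone_in_exposed_count(self):
        values = [prr(ContingencyTable(a1, 100, 5, 80)) for a1 in range(1, 101)]
        assert all(x <= y for x, y in zip(values, values[1:]))


class TestPrrCi:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((1046, 2076, 4, 92), (4.44, 30.25)),
            ((727, 2076, 3, 92), (3.52, 32.74)),
            # closed form at PRR = 1: exp(+/- 1.96 * sqrt(0.18))
            ((10, 100, 10, 100), (0.4354, 2.2969)),
        ],
    )
    def test_delta_method_bounds(self, cells, expected):
        lo, hi = prr_ci(ContingencyTable(*cells))
        nd = 4 if expected[0] < 1 else 2
        assert round_half_up(lo, nd) == expected[0]
        assert round_half_up(hi, nd) == expected[1]

    def test_undefined_on_zero_cells(self):
        assert prr_ci(ContingencyTable(0, 60, 8, 99)) is None
        assert prr_ci(ContingencyTable(956, 2076, 0, 92)) is None

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.tuples(st.integers(1, 300), st.integers(0, 300),
                     st.integers(1, 300), st.integers(0, 300)))
    def test_interval_covers_the_point(self, cells):
        a1, ea, b1, eb = cells
        t = ContingencyTable(a1, a1 + ea, b1, b1 + eb)
        lo, hi = prr_ci(t)
        assert lo <= prr(t) <= hi


class TestFisher:
    @pytest.mark.parametrize(
        "cells,decimals,expected",
        [
            ((3, 60, 5, 99), 2, 1.00),
            ((0, 60, 9, 99), 3, 0.027),
            ((1, 2, 1, 2), 2, 1.00),
        ],
    )
    def test_published_and_symmetric_examples(self, cells, decimals, expected):
        p = fisher_exact_two_tailed(ContingencyTable(*cells))
        assert round_half_up(p, decimals) == expected

    def test_matches_exact_enumeration_on_small_tables(self):
        for cells in [(3, 7, 2, 9), (0, 5, 4, 6), (2, 2, 3, 8), (1, 12, 6, 10)]:
            p = fisher_two_tailed_cells(*cells)
            assert p == pytest.approx(float(fisher_enumeration(*cells)), rel=1e-9)

    def test_agrees_with_scipy_on_the_same_cells(self):
        for cells in [(3, 60, 5, 99), (671, 1405, 1, 91), (11, 49, 2, 97)]:
            table = [[cells[0], cells[1]], [cells[2], cells[3]]]
            assert fisher_two_tailed_cells(*cells) == pytest.approx(
                scipy_fisher(table).pvalue, rel=1e-6
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(st.integers(0, 15), st.integers(1, 15),
                     st.integers(0, 15), st.integers(1, 15)))
    def test_symmetry_under_row_swap(self, cells):
        a1, a0x, b1, b0x = cells
        t = ContingencyTable(a1, a1 + a0x, b1, b1 + b0x)
        swapped = ContingencyTable(b1, b1 + b0x, a1, a1 + a0x)
        assert fisher_exact_two_tailed(t) == pytest.approx(
            fisher_exact_two_tailed(swapped), rel=1e-9
        )


class TestGenderComposition:
    def test_published_rows(self):
        fin = gender_composition(2076, 60, 1_750_808, 2_818_346)
        assert round_half_up(fin.pct_male, 1) == 97.2
        assert round_half_up(fin.or_mf, 2) == 55.70
        assert fin.p_value < 1e-100  # printed as "0"
        minox = gender_composition(92, 99, 1_750_808, 2_818_346)
        assert round_half_up(minox.or_mf, 2) == 1.50
        assert round_half_up(minox.p_value, 4) == 0.0058
        assert round_half_up(
            100 * 1_750_808 / (1_750_808 + 2_818_346), 1
        ) == 38.3

    def test_self_reference_gives_unit_odds_ratio(self):
        row = gender_composition(34, 55, 34, 55)
        assert row.or_mf == pytest.approx(1.0)
        assert row.p_value == pytest.approx(1.0)

    def test_no_female_cases_leaves_or_undefined(self):
        assert gender_composition(10, 0, 5, 5).or_mf is None

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            gender_composition(1, 1, 0, 5)


class TestCompareDrugs:
    def test_published_male_row(self, male_cohorts):
        rows = {r.event_term: r for r in compare_drugs(*male_cohorts)}
        anxiety = rows["ANXIETY"]
        assert round_half_up(100 * anxiety.prop_a, 2) == 32.32
        assert round_half_up(100 * anxiety.prop_b, 2) == 1.09
        assert round_half_up(anxiety.prr, 2) == 29.74
        assert anxiety.stars == "***"

    def test_published_female_row(self, female_cohorts):
        rows = {r.event_term: r for r in compare_drugs(*female_cohorts)}
        abortion = rows["ABORTION INDUCED"]
        assert abs(abortion.prr - 9.07) <= 0.01
        assert abortion.stars == "**"

    def test_default_row_set_is_union_of_top10(self, male_cohorts):
        rows = compare_drugs(*male_cohorts)
        assert len(rows) == 16  # published male table row count
        assert [r.event_term for r in rows] == sorted(r.event_term for r in rows)

    def test_event_absent_from_both_cohorts(self, male_cohorts):
        (row,) = compare_drugs(*male_cohorts, events=["NOT A REAL EVENT"])
        assert row.table.a1 == row.table.b1 == 0
        assert row.prr is None
        assert row.p_value == pytest.approx(1.0)

    def test_mixed_sex_comparison_rejected(self, male_cohorts, female_cohorts):
        with pytest.raises(ValueError, match="sex"):
            compare_drugs(male_cohorts[0], female_cohorts[1])


@pytest.mark.parametrize(
    "p,expected",
    [(0.9, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "")],
)
def test_star_thresholds(p, expected):
    assert stars_for(p) == expected
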