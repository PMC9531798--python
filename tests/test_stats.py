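"""Contingency tests, allele frequencies, survival and t-test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kdrsurv import reference_data as ref
from kdrsurv.stats import (allele_frequency, compare_categories,
                           fisher_one_sided, format_p, pearson_chi2,
                           run_test, select_test, survival_rates, unpaired_t)


def fisher_oracle(table) -> Fraction:
    """Exact-rational one-sided Fisher p by enumerating every 2x2 table with
    the observed margins and summing hypergeometric probabilities at least
    as extreme in the category-enriched-in-group-2 direction."""
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    n_total = a + b + c + d
    cat_total = c + d
    g2_total = b + d
    denom = comb(n_total, g2_total)
    p = Fraction(0)
    for x in range(cat_total + 1):  # x = category count in group 2
        wild_in_g2 = g2_total - x
        if not 0 <= wild_in_g2 <= a + b:
            continue
        if x >= d:
            p += Fraction(comb(cat_total, x)
                          * comb(n_total - cat_total, wild_in_g2), denom)
    return p


PRINTED_TABLES = [
    [[127, 100], [15, 45]], [[127, 100], [6, 27]],
    [[108, 73], [34, 59]], [[108, 73], [6, 40]],
    [[103, 96], [36, 59]], [[103, 96], [9, 17]],
    [[139, 137], [9, 31]], [[139, 137], [0, 4]],
    [[74, 12], [4, 22]], [[74, 12], [0, 3]],
    [[60, 3], [18, 23]], [[60, 3], [0, 11]],
    [[64, 16], [12, 19]], [[64, 16], [2, 2]],
    [[64, 25], [14, 8]], [[64, 25], [0, 4]],
    [[72, 48], [9, 17]], [[72, 48], [0, 4]],
    [[45, 0], [1, 1]], [[45, 0], [2, 2]], [[45, 0], [0, 14]],
]


@pytest.mark.parametrize("table", PRINTED_TABLES)
def test_fisher_matches_exact_enumeration_oracle(table):
    got = fisher_one_sided(table).p_value
    expected = float(fisher_oracle(table))
    assert got == pytest.approx(expected, rel=1e-9)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.integers(0, 40), min_size=4, max_size=4))
def test_fisher_matches_oracle_on_random_tables(cells):
    table = [cells[:2], cells[2:]]
    if sum(cells) == 0:
        return
    assert fisher_one_sided(table).p_value == pytest.approx(
        float(fisher_oracle(table)), rel=1e-9)


def test_single_draw_fisher_has_closed_form():
    # one alive specimen among 47, category holds the single group-2 slot
    # with P = 2/47 under the hypergeometric
    res = fisher_one_sided([[45, 0], [1, 1]])
    assert res.p_value == pytest.approx(2 / 47)
    assert res.p_display == "0.0426"


class TestChiSquare:
    def test_reproduces_published_heterozygote_comparison(self):
        res = pearson_chi2([[103, 96], [36, 59]])
        assert res.statistic == pytest.approx(4.96, abs=0.005)
        assert res.p_display == "0.0260"

    def test_no_association_gives_zero_statistic(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_invariant_to_transposition_and_row_swap(self):
        t = np.array([[72, 48], [9, 17]])
        base = pearson_chi2(t).statistic
        assert pearson_chi2(t.T).statistic == pytest.approx(base)
        assert pearson_chi2(t[::-1]).statistic == pytest.approx(base)
        assert pearson_chi2(t[:, ::-1]).statistic == pytest.approx(base)

    def test_more_extreme_off_diagonal_lowers_p_at_fixed_margins(self):
        # move one unit from the diagonal to the off-diagonal cells
        tables = [[[30, 20], [20, 30]], [[35, 15], [15, 35]],
                  [[40, 10], [10, 40]]]
        ps = [pearson_chi2(t).p_value for t in tables]
        assert ps[0] > ps[1] > ps[2]

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 7]])


@pytest.mark.parametrize("table, expected", [
    ([[139, 137], [0, 4]], "fisher_one_sided"),   # min expected ~1.87
    ([[103, 96], [36, 59]], "chi_square"),        # min expected ~44.9
    ([[72, 48], [9, 17]], "chi_square"),          # min expected ~11.6
    ([[45, 0], [2, 2]], "fisher_one_sided"),
])
def test_expected_count_rule_selects_the_published_test(table, expected):
    assert select_test(table) == expected
    assert run_test(table).test_used == expected


@pytest.mark.parametrize("counts, expected", [
    ((73, 59, 40), 139 / 344),   # October 1016 -> 0.40
    ((127, 15, 6), 27 / 296),    # March 989 -> 0.09
    ((50, 0, 0), 0.0),
    ((0, 0, 10), 1.0),
])
def test_allele_frequency_from_zygosity_counts(counts, expected):
    assert allele_frequency(*counts) == pytest.approx(expected)


def test_allele_frequency_empty_group_raises():
    with pytest.raises(ValueError):
        allele_frequency(0, 0, 0)


def test_compare_categories_reports_share_change_and_p():
    tidy = ref.genotype_counts_frame(ref.FIELD_GENOTYPE_COUNTS,
                                     ref.FIELD_GROUPS)
    results = {r.category: r for r in compare_categories(
        tidy, ref.WILD_GENOTYPE, group_order=list(ref.FIELD_GROUPS))}
    top = results["PGFD/SVCD"]
    assert top.share_change == pytest.approx(16.5)
    assert top.p_value < 0.00005
    assert "SVFD/SVFD" not in results
    # a category absent from both groups would be skipped; all present here
    assert len(results) == len(ref.FIELD_GENOTYPE_COUNTS) - 1


def test_compare_identical_groups_is_null():
    import pandas as pd
    tidy = pd.DataFrame([
        {"category": "SVFD/SVFD", "group": "a", "count": 30},
        {"category": "SVFD/SVFD", "group": "b", "count": 30},
        {"category": "X", "group": "a", "count": 30},
        {"category": "X", "group": "b", "count": 30}])
    (res,) = compare_categories(tidy, "SVFD/SVFD", group_order=["a", "b"])
    assert res.p_value == pytest.approx(1.0) or res.p_value > 0.5


def test_survival_rates_match_published_rows():
    import pandas as pd
    frame = pd.DataFrame([
        {"category": "SVCD/SVFD", "dead": 12, "alive": 1},
        {"category": "PGFD/SVCD", "dead": 0, "alive": 14},
        {"category": "SGFY/SVFD", "dead": 13, "alive": 0}])
    out = survival_rates(frame).set_index("category")["survival_pct"]
    assert out["SVCD/SVFD"] == pytest.approx(7.7)
    assert out["PGFD/SVCD"] == pytest.approx(100.0)
    assert out["SGFY/SVFD"] == pytest.approx(0.0)


class TestUnpairedT:
    def test_identical_vectors_are_null(self):
        assert unpaired_t([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == (0.0, 1.0)

    def test_separated_groups_reject(self):
        t, p = unpaired_t([0.0, 0.01, 0.0], [1.0, 0.99, 1.0])
        assert p < 1e-6

    def test_null_rejection_rate_is_nominal(self):
        # simulation oracle: under H0 the rejection rate at alpha=0.05
        # stays within Monte-Carlo error of 0.05
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 800
        for _ in range(n_rep):
            a = rng.normal(0.2, 0.05, size=9)
            b = rng.normal(0.2, 0.05, size=9)
            _, p = unpaired_t(a, b)
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 4 * se


@pytest.mark.parametrize("p, text", [
    (0.000049, "0.0000"), (0.00005, "0.0001"), (0.0259951, "0.0260"),
    (1.0, "1.0000")])
def test_p_value_presentation_convention(p, text):
    assert format_p(p) == text
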