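"""Association statistics: Abbott, tables, tests, CIs, multiple comparisons."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from kdrkit.simulate import TABLE2_COUNTS
from kdrkit.stats import (
    ContingencyTable,
    DegenerateTableError,
    abbott_correction,
    allele_count_table,
    allele_homogeneity_test,
    chi_square_rxc,
    fisher_exact_2x2,
    genotype_group_table,
    marascuilo_pairwise,
    odds_ratio,
    sequential_bonferroni,
    survival_proportion_ci,
)

# published allele/group counts used as module-level expectations
TABLE1 = {
    "DDT": {"alive": (12, 93, 61), "dead": (82, 68, 16)},
    "deltamethrin": {"alive": (11, 40, 43), "dead": (42, 44, 38)},
    "alpha-cypermethrin": {"alive": (3, 34, 9), "dead": (176, 83, 15)},
}
GROUPS = {
    "DDT": {"alive": (9, 28, 33, 13), "dead": (62, 15, 6, 0)},
    "deltamethrin": {"alive": (11, 11, 18, 7), "dead": (36, 8, 16, 2)},
    "alpha-cypermethrin": {"alive": (3, 13, 5, 2), "dead": (119, 15, 2, 1)},
}


# ---------------------------------------------------------------------------
# Abbott correction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "test,control,value,verdict",
    [
        (43.0, 0.0, 43.0, "uncorrected"),
        (50.0, 20.0, 37.5, "corrected"),
        (60.0, 25.0, None, "discard"),
        (84.0, 4.9, 84.0, "uncorrected"),
    ],
)
def test_abbott_correction_gating(test, control, value, verdict):
    res = abbott_correction(test, control)
    assert res.verdict == verdict
    if value is None:
        assert res.value is None
    else:
        assert res.value == pytest.approx(value)


def test_abbott_rejects_out_of_range_and_total_control_mortality():
    with pytest.raises(ValueError):
        abbott_correction(101.0, 0.0)
    with pytest.raises(ValueError):
        abbott_correction(50.0, -1.0)
    with pytest.raises(ValueError):
        abbott_correction(100.0, 100.0, discard_above=100.0)


# ---------------------------------------------------------------------------
# Table builders (against the published counts)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("insecticide", sorted(TABLE1))
def test_allele_table_reproduces_published_counts(fixture_df, insecticide):
    table = allele_count_table(fixture_df, insecticide)
    assert list(table.table.columns) == ["Leu", "Ser", "Phe"]
    for outcome in ("alive", "dead"):
        assert tuple(table.table.loc[outcome]) == TABLE1[insecticide][outcome]
    # each individual contributes two alleles
    n_flies = len(
        fixture_df[
            (fixture_df.insecticide == insecticide) & (fixture_df.role == "test")
        ]
    )
    assert table.total == 2 * n_flies


@pytest.mark.parametrize("insecticide", sorted(GROUPS))
def test_group_table_reproduces_published_counts(fixture_df, insecticide):
    table = genotype_group_table(fixture_df, insecticide)
    for outcome in ("alive", "dead"):
        assert tuple(table.table.loc[outcome]) == GROUPS[insecticide][outcome]


def test_allele_table_derivable_from_genotype_counts(fixture_df):
    # 2 * homozygote + each heterozygote per allele, e.g. DDT alive Leu = 2*3+4+2
    for ins, by_outcome in TABLE2_COUNTS.items():
        table = allele_count_table(fixture_df, ins)
        for outcome, cells in by_outcome.items():
            for residue in ("Leu", "Ser", "Phe"):
                expected = 2 * cells[f"{residue}/{residue}"] + sum(
                    c
                    for label, c in cells.items()
                    if residue in label.split("/")
                    and label != f"{residue}/{residue}"
                )
                assert table.table.loc[outcome, residue] == expected


def test_leu_split_exposes_fine_heterogeneity(fixture_df):
    fine = genotype_group_table(fixture_df, "deltamethrin", leu_split=True)
    assert tuple(fine.table.loc["alive", ["Leu/Leu", "Leu/Ser", "Leu/Phe"]]) == (0, 0, 11)


def test_empty_input_gives_all_zero_table():
    empty = pd.DataFrame(
        {"id": [], "insecticide": [], "outcome": [], "role": [], "genotype": []}
    )
    table = allele_count_table(empty, "DDT")
    assert table.total == 0


def test_single_specimen_lands_in_one_cell():
    df = pd.DataFrame(
        [{"id": "x", "insecticide": "DDT", "outcome": "alive",
          "role": "test", "genotype": "TCA/TTT"}]
    )
    table = genotype_group_table(df, "DDT")
    assert table.table.loc["alive", "Ser/Phe"] == 1
    assert table.total == 1


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable(pd.DataFrame([[1, -1], [0, 2]]))


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


def _pearson_oracle(arr):
    arr = np.asarray(arr, dtype=float)
    total = arr.sum()
    stat = 0.0
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            e = arr[i].sum() * arr[:, j].sum() / total
            stat += (arr[i, j] - e) ** 2 / e
    return stat


@pytest.mark.parametrize(
    "insecticide,expected",
    [("DDT", 75.2), ("deltamethrin", 14.9), ("alpha-cypermethrin", 62.6)],
)
def test_group_chi_square_matches_published(fixture_df, insecticide, expected):
    table = genotype_group_table(fixture_df, insecticide)
    res = chi_square_rxc(table)
    assert res.df == 3
    assert round(res.statistic, 1) == expected


def test_chi_square_proportional_rows_is_null():
    res = chi_square_rxc([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_chi_square_zero_margin_names_the_level():
    table = pd.DataFrame(
        [[5, 0], [3, 0]], index=["alive", "dead"], columns=["Ser", "Phe"]
    )
    with pytest.raises(DegenerateTableError, match="Phe"):
        chi_square_rxc(ContingencyTable(table))


@given(
    st.lists(
        st.lists(st.integers(1, 40), min_size=2, max_size=4),
        min_size=2,
        max_size=4,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_chi_square_equals_brute_force_pearson(rows):
    arr = np.array(rows)
    res = chi_square_rxc(arr)
    assert res.statistic == pytest.approx(_pearson_oracle(arr), rel=1e-10)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def fisher_enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration with fixed margins (independent route)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    acc = sum(
        p
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (p := comb(r1, k) * comb(r2, c1 - k)) <= obs
    )
    return acc / denom


def test_fisher_phe_vs_ser_ddt_matches_published_magnitude(fixture_df):
    table = allele_count_table(fixture_df, "DDT").table[["Phe", "Ser"]]
    res = fisher_exact_2x2(table)
    assert res.pvalue == pytest.approx(0.0013, abs=2e-4)


def test_fisher_identical_rows_is_one():
    assert fisher_exact_2x2([[7, 11], [7, 11]]).pvalue == pytest.approx(1.0)


@given(
    st.tuples(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    ).filter(lambda t: 0 < sum(t) <= 30)
)
def test_fisher_matches_enumeration_for_small_tables(cells):
    a, b, c, d = cells
    got = fisher_exact_2x2([[a, b], [c, d]]).pvalue
    assert got == pytest.approx(fisher_enumeration_oracle(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# odds ratio
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "table,expected",
    [
        ([[93, 12], [68, 82]], 9.35),   # Ser vs Leu, DDT
        ([[40, 11], [44, 42]], 3.47),   # Ser vs Leu, deltamethrin
        ([[61, 93], [16, 68]], 2.79),   # Phe vs Ser, DDT
    ],
)
def test_cross_product_odds_ratios_match_published(table, expected):
    res = odds_ratio(table)
    assert res.estimator == "cross-product"
    assert round(res.oddsratio, 2) == expected
    assert res.ci_low < res.oddsratio < res.ci_high


def test_symmetric_table_or_is_one():
    assert odds_ratio([[9, 9], [9, 9]]).oddsratio == pytest.approx(1.0)


def test_zero_cell_uses_haldane_adjustment():
    res = odds_ratio([[13, 9], [0, 62]])
    assert res.estimator == "cross-product-haldane"
    assert res.oddsratio > 1


def test_fully_degenerate_table_rejected():
    with pytest.raises(ValueError):
        odds_ratio([[0, 5], [0, 7]])


@given(
    st.tuples(
        st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50)
    )
)
def test_or_of_column_swapped_table_is_reciprocal(cells):
    a, b, c, d = cells
    fwd = odds_ratio([[a, b], [c, d]]).oddsratio
    swapped = odds_ratio([[b, a], [d, c]]).oddsratio
    assert fwd == pytest.approx(1.0 / swapped)


# ---------------------------------------------------------------------------
# Wilson continuity-corrected proportion CI
# ---------------------------------------------------------------------------


def test_survival_proportion_examples():
    ser = survival_proportion_ci(28, 43)
    assert ser.estimate == pytest.approx(0.65, abs=0.005)
    phe = survival_proportion_ci(13, 13)
    assert phe.estimate == 1.0 and phe.ci_high == 1.0
    none_alive = survival_proportion_ci(0, 20)
    assert none_alive.ci_low == 0.0


def test_wilson_cc_reproduces_published_sensitivity_interval():
    ci = survival_proportion_ci(74, 83)
    assert (round(100 * ci.ci_low), round(100 * ci.ci_high)) == (80, 95)


@given(st.integers(1, 30), st.integers(1, 6))
def test_ci_widens_as_n_decreases_at_fixed_estimate(k, factor):
    n = 2 * k  # fixed p-hat = 0.5
    small = survival_proportion_ci(k, n)
    large = survival_proportion_ci(k * factor, n * factor)
    assert (small.ci_high - small.ci_low) >= (large.ci_high - large.ci_low) - 1e-12


def test_survival_proportion_input_validation():
    with pytest.raises(ValueError):
        survival_proportion_ci(1, 0)
    with pytest.raises(ValueError):
        survival_proportion_ci(5, 4)


# ---------------------------------------------------------------------------
# Marascuilo-McSweeney
# ---------------------------------------------------------------------------


def test_marascuilo_equal_proportions_not_significant():
    comps = marascuilo_pairwise([(5, 10), (10, 20), (20, 40)])
    assert all(not c.significant for c in comps)
    assert all(c.pvalue > 0.9 for c in comps)


def test_marascuilo_reconstructs_published_leu_phe_contrast():
    # pooled Leu/Leu+Leu/Ser (0/18) vs Leu/Phe (11/29) within a K=5 family
    groups = [(0, 18), (11, 29), (11, 19), (18, 34), (7, 9)]
    comps = marascuilo_pairwise(groups, labels=["LeuLeu+LeuSer", "LeuPhe",
                                                "SerSer", "SerPhe", "PhePhe"])
    target = next(
        c for c in comps if {c.label_i, c.label_j} == {"LeuLeu+LeuSer", "LeuPhe"}
    )
    assert round(target.pvalue, 4) == 0.0014
    assert target.significant


@given(
    st.tuples(st.integers(0, 30), st.integers(1, 30)).filter(lambda t: t[0] <= t[1]),
    st.tuples(st.integers(0, 30), st.integers(1, 30)).filter(lambda t: t[0] <= t[1]),
)
def test_marascuilo_k2_decision_matches_two_proportion_z_test(g1, g2):
    alpha = 0.05
    (k1, n1), (k2, n2) = g1, g2
    (comp,) = marascuilo_pairwise([g1, g2], alpha=alpha)
    p1, p2 = k1 / n1, k2 / n2
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        return
    z = abs(p1 - p2) / math.sqrt(var)
    assert comp.significant == (z > sps.norm.ppf(1 - alpha / 2))


def test_marascuilo_boundary_pair_is_flagged_not_crashed():
    comps = marascuilo_pairwise([(0, 10), (10, 10)])
    (c,) = comps
    assert c.boundary and 0 <= c.pvalue < 0.05


def test_marascuilo_input_validation():
    with pytest.raises(ValueError):
        marascuilo_pairwise([(1, 2)])
    with pytest.raises(ValueError):
        marascuilo_pairwise([(0, 0), (1, 2)])


# ---------------------------------------------------------------------------
# sequential Bonferroni (Holm)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pvalues,expected",
    [
        ([0.01], [True]),
        ([0.001, 0.02, 0.04], [True, True, True]),
        ([0.04, 0.04, 0.04], [False, False, False]),
        ([0.001, 0.03, 0.04], [True, False, False]),
    ],
)
def test_holm_decisions(pvalues, expected):
    decisions = sequential_bonferroni(pvalues, alpha=0.05)
    assert [d.reject for d in decisions] == expected


def test_holm_empty_list():
    assert sequential_bonferroni([]) == []


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
def test_holm_matches_statsmodels_and_is_monotone(pvalues):
    ours = [d.reject for d in sequential_bonferroni(pvalues, alpha=0.05)]
    theirs = list(multipletests(pvalues, alpha=0.05, method="holm")[0])
    assert ours == theirs
    by_p = sorted(zip(pvalues, ours))
    seen_retain = False
    for _, reject in by_p:
        if not reject:
            seen_retain = True
        assert not (seen_retain and reject)


# ---------------------------------------------------------------------------
# TTC vs TTT pooling check
# ---------------------------------------------------------------------------


def test_allele_homogeneity_identical_distributions():
    results, min_p = allele_homogeneity_test({"DDT": [[10, 10], [5, 5]]})
    assert min_p == pytest.approx(1.0)
    assert results["DDT"].pvalue == pytest.approx(1.0)


def test_allele_homogeneity_strong_association_warns():
    with pytest.warns(UserWarning, match="pooling"):
        results, min_p = allele_homogeneity_test({"DDT": [[30, 2], [2, 30]]})
    assert min_p < 0.05
    assert min_p == pytest.approx(
        fisher_enumeration_oracle(30, 2, 2, 30), abs=1e-9
    )
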