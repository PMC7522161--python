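"""Group-statistics tests against independent enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from endostress.features import build_feature_table
from endostress.stats import (ComparisonPlan, compare_groups, fisher_exact,
                              mann_whitney_u, pearson_chi_square, two_sample_t)

# ---------------------------------------------------------------------------
# Mann-Whitney U


def enum_u_test(a, b, alternative):
    """Brute-force exact U test: enumerate every group labelling."""
    pooled = np.array(list(a) + list(b), float)
    n_a, n = len(a), len(pooled)

    def u_stat(idx_a):
        av = pooled[list(idx_a)]
        bv = np.delete(pooled, list(idx_a))
        return ((av[:, None] > bv[None, :]).sum()
                + 0.5 * (av[:, None] == bv[None, :]).sum())

    u_obs = u_stat(range(n_a))
    us = np.array([u_stat(c) for c in itertools.combinations(range(n), n_a)])
    p_less = np.mean(us <= u_obs)
    p_greater = np.mean(us >= u_obs)
    if alternative == "less":
        return u_obs, p_less
    if alternative == "greater":
        return u_obs, p_greater
    return u_obs, min(1.0, 2 * min(p_less, p_greater))


def test_u_test_worked_example():
    """Fully separated groups of 3: U=0 and one-sided p = 1/20."""
    res = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
    assert res.statistic == 0.0
    assert res.p_one_sided == pytest.approx(0.05, abs=1e-12)
    assert "exact" in res.method


def test_u_test_identical_multisets_give_p_one():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3], alternative="two-sided")
    assert res.p_two_sided == pytest.approx(1.0)


@pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
def test_u_test_matches_enumeration_for_small_groups(alternative):
    """Exact-path p-values equal full enumeration for all sizes <= 5."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        n_a, n_b = rng.integers(1, 6), rng.integers(1, 6)
        vals = rng.permutation(30)[: n_a + n_b].astype(float)
        a, b = vals[:n_a], vals[n_a:]
        u, p = enum_u_test(a, b, alternative)
        res = mann_whitney_u(a, b, alternative=alternative)
        got = res.p_two_sided if alternative == "two-sided" else res.p_one_sided
        assert res.statistic == pytest.approx(u, abs=1e-12)
        assert got == pytest.approx(p, abs=1e-12)


def test_u_test_swap_identity():
    """Swapping groups flips a one-sided exact p up to the point mass at U."""
    a, b = [3.0, 9.0, 1.0], [4.0, 7.0, 8.0, 2.0]
    p_less = mann_whitney_u(a, b, alternative="less").p_one_sided
    p_swapped = mann_whitney_u(b, a, alternative="less").p_one_sided
    _, point = enum_u_test(a, b, "less")
    _, p_ge = enum_u_test(a, b, "greater")
    # P(U_b <= u_b) = P(U_a >= u_a); and P(<=) + P(>=) = 1 + P(=)
    assert p_swapped == pytest.approx(p_ge, abs=1e-12)
    assert p_less + p_swapped == pytest.approx(1.0 + (p_less + p_ge - 1.0), abs=1e-12)


def test_u_test_statistic_complement():
    """U_a + U_b = n_a * n_b, with ties contributing one half."""
    rng = np.random.default_rng(7)
    a = rng.integers(0, 5, 8).astype(float)
    b = rng.integers(0, 5, 11).astype(float)
    ua = mann_whitney_u(a, b).statistic
    ub = mann_whitney_u(b, a).statistic
    assert ua + ub == pytest.approx(len(a) * len(b))


finite_floats = st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, allow_infinity=False)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(a=st.lists(finite_floats, min_size=1, max_size=15),
       b=st.lists(finite_floats, min_size=1, max_size=15))
def test_u_test_invariant_under_monotone_transform(a, b):
    """A rank test depends only on orderings: applying a strictly
    increasing transform to all values leaves U and p unchanged."""
    base = mann_whitney_u(a, b, alternative="less")
    # x -> 4x is strictly increasing and exact in floating point, so the
    # tie structure is preserved bit-for-bit
    transformed = mann_whitney_u([4.0 * x for x in a], [4.0 * x for x in b],
                                 alternative="less")
    assert transformed.statistic == pytest.approx(base.statistic)
    assert transformed.p_one_sided == pytest.approx(base.p_one_sided)
    assert 0 <= base.p_one_sided <= 1


def test_u_test_rejects_empty_group():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0, 2.0])


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_study_contingency_tables():
    """Printed cohort-characteristics p-values reproduce to three decimals."""
    cases = {(0.886,): [[51, 47], [50, 48]],
             (0.646,): [[65, 33], [68, 30]],
             (0.489,): [[88, 10], [84, 13]]}
    for (expected,), table in cases.items():
        res = pearson_chi_square(table)
        assert round(res.p_two_sided, 3) == expected


def test_chi_square_equal_proportions_is_null():
    res = pearson_chi_square([[10, 20], [30, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_two_sided == pytest.approx(1.0)


def test_chi_square_closed_form_diagonal():
    """chi2 = N(ad-bc)^2 / (r1 r2 c1 c2) on a diagonal table."""
    assert pearson_chi_square([[10, 0], [0, 10]]).statistic == pytest.approx(20.0)


def test_chi_square_invariances():
    t = np.array([[13, 7], [5, 21]])
    base = pearson_chi_square(t).statistic
    assert pearson_chi_square(t.T).statistic == pytest.approx(base)
    assert pearson_chi_square(t[::-1, ::-1]).statistic == pytest.approx(base)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        pearson_chi_square([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# Fisher


def test_fisher_diagonal_3s():
    """[[3,0],[0,3]]: only 2 of the 20 margin-fixed tables are as extreme."""
    assert fisher_exact([[3, 0], [0, 3]]).p_two_sided == pytest.approx(0.1)


def test_fisher_identical_columns_is_null():
    assert fisher_exact([[5, 5], [9, 9]]).p_two_sided == pytest.approx(1.0)


def test_fisher_p_at_least_point_probability():
    rng = np.random.default_rng(11)
    for _ in range(50):
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        a, b = t[0]
        c, d = t[1]
        point = hypergeom.pmf(a, t.sum(), a + b, a + c)
        assert fisher_exact(t).p_two_sided >= point - 1e-12


def test_fisher_chi_square_agree_for_large_cells():
    """With all cells >= 20 the exact and asymptotic tests agree closely on
    average; individual tables can still differ by ~0.1 because the
    two-sided Fisher convention (sum of no-more-probable tables) is not the
    chi-square's symmetric tail."""
    rng = np.random.default_rng(23)
    diffs = []
    for _ in range(50):
        t = rng.integers(20, 80, size=(2, 2))
        diffs.append(abs(fisher_exact(t).p_two_sided - pearson_chi_square(t).p_two_sided))
    assert np.mean(diffs) < 0.05
    assert max(diffs) < 0.15


# ---------------------------------------------------------------------------
# t-test


def test_t_test_identical_groups():
    res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_two_sided == pytest.approx(1.0)


def test_t_test_rejects_zero_variances():
    with pytest.raises(ValueError):
        two_sample_t([0.0, 0.0], [1.0, 1.0])


def test_welch_matches_direct_formula():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 14), rng.normal(0.4, 2, 9)
    res = two_sample_t(a, b, variant="welch")
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    assert res.statistic == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)


# ---------------------------------------------------------------------------
# comparison table


def _toy_features(sexes=("female", "male")):
    rng = np.random.default_rng(99)
    rows = []
    for g, n in (("control", 8), ("music", 8)):
        for i in range(n):
            rows.append({"patient_id": f"{g[0]}{i}", "group": g,
                         "sex": sexes[i % len(sexes)], "channel": "femg_zygomaticus",
                         "anchor": "start",
                         "value": rng.normal(7 if g == "control" else 5, 1),
                         "unit": "uV", "qc": "kept"})
    return build_feature_table(rows)


def test_compare_groups_is_pure():
    ft = _toy_features()
    t1 = compare_groups(ft)
    t2 = compare_groups(ft)
    pd.testing.assert_frame_equal(t1, t2)


def test_compare_groups_single_sex_cohort():
    """Opposite-sex stratum is not computable; 'all' stays intact."""
    ft = _toy_features(sexes=("female",))
    table = compare_groups(ft)
    male = table[table["stratum"] == "male"].iloc[0]
    both = table[table["stratum"] == "all"].iloc[0]
    assert np.isnan(male["p_one_sided"])
    assert np.isfinite(both["p_one_sided"])
    assert both["n_control"] == 8 and both["n_music"] == 8


def test_compare_groups_direction_is_declared_not_inferred():
    """A one-sided test in the wrong direction must not turn significant."""
    ft = _toy_features()  # music below control by construction
    up = compare_groups(ft, ComparisonPlan(directions={"femg_zygomaticus": "greater"}))
    down = compare_groups(ft, ComparisonPlan(directions={"femg_zygomaticus": "less"}))
    p_up = up[up["stratum"] == "all"].iloc[0]["p_one_sided"]
    p_down = down[down["stratum"] == "all"].iloc[0]["p_one_sided"]
    assert p_down < 0.05 < p_up
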