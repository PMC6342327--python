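"""Exact test, conditional-MLE odds ratio and BY adjustment.

The implementation is cross-checked against independent routes: direct
enumeration of the hypergeometric support, grid maximisation of the
noncentral hypergeometric likelihood, scipy's Fisher test and conditional
odds-ratio estimator, and statsmodels' FDR procedures.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio
from statsmodels.stats.multitest import multipletests

from gerotarget.stats import (
    adjust_by,
    conditional_mle_odds_ratio,
    fisher_exact,
    sample_odds_ratio,
)

# ---------------------------------------------------------------- oracles


def enum_pmf(row1, col1, total):
    """Central hypergeometric pmf over the k support, by log-binomials."""
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    logp = (
        gammaln(col1 + 1) - gammaln(xs + 1) - gammaln(col1 - xs + 1)
        + gammaln(total - col1 + 1) - gammaln(row1 - xs + 1)
        - gammaln(total - col1 - row1 + xs + 1)
        - (gammaln(total + 1) - gammaln(row1 + 1) - gammaln(total - row1 + 1))
    )
    return xs, np.exp(logp)


def enum_two_sided(k, l, m, n):
    xs, pmf = enum_pmf(k + l, k + m, k + l + m + n)
    obs = pmf[list(xs).index(k)]
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


def enum_greater(k, l, m, n):
    xs, pmf = enum_pmf(k + l, k + m, k + l + m + n)
    return float(pmf[xs >= k].sum())


def grid_cmle(k, l, m, n):
    """Maximise the noncentral hypergeometric likelihood over a log grid."""
    row1, col1, total = k + l, k + m, k + l + m + n
    xs, _ = enum_pmf(row1, col1, total)
    logw = (
        gammaln(col1 + 1) - gammaln(xs + 1) - gammaln(col1 - xs + 1)
        + gammaln(total - col1 + 1) - gammaln(row1 - xs + 1)
        - gammaln(total - col1 - row1 + xs + 1)
    )
    grid = np.linspace(math.log(1e-8), math.log(1e8), 20001)
    best, best_ll = None, -np.inf
    for lp in grid:
        terms = logw + xs * lp
        z = terms.max() + np.log(np.exp(terms - terms.max()).sum())
        ll = logw[list(xs).index(k)] + k * lp - z
        if ll > best_ll:
            best_ll, best = ll, lp
    return math.exp(best)


def random_tables(n, max_margin=30, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        k, l, m, nn = rng.integers(0, max_margin + 1, size=4)
        if (k + l) and (k + m) and (l + nn) and (m + nn):
            out.append((int(k), int(l), int(m), int(nn)))
    return out


# ----------------------------------------------------------- fisher exact


class TestFisherExact:
    def test_greater_matches_enumeration_and_scipy(self):
        for k, l, m, n in random_tables(300, seed=1):
            p = fisher_exact(k, l, m, n, "greater")
            assert p == pytest.approx(enum_greater(k, l, m, n), rel=1e-10)
            assert p == pytest.approx(
                scipy_fisher([[k, l], [m, n]], alternative="greater").pvalue,
                rel=1e-8,
            )

    def test_two_sided_matches_enumeration_and_scipy(self):
        for k, l, m, n in random_tables(300, seed=2):
            p = fisher_exact(k, l, m, n, "two_sided_min_likelihood")
            assert p == pytest.approx(enum_two_sided(k, l, m, n), rel=1e-10)
            assert p == pytest.approx(
                scipy_fisher([[k, l], [m, n]]).pvalue, rel=1e-7
            )

    def test_modal_symmetric_table_has_p_one(self):
        assert fisher_exact(2, 2, 2, 2, "two_sided_min_likelihood") == 1.0

    def test_large_table_no_overflow(self):
        # margins in the thousands, the scale of a real term universe
        p = fisher_exact(66, 150, 388, 2221, "greater")
        assert 0 < p < 1e-7

    def test_greater_nonincreasing_in_k_at_fixed_margins(self):
        row1, col1, total = 12, 15, 60
        ps = [
            fisher_exact(k, row1 - k, col1 - k, total - row1 - col1 + k, "greater")
            for k in range(0, min(row1, col1) + 1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_two_sided_bounded_by_point_probability_and_one(self):
        for k, l, m, n in random_tables(100, seed=3):
            xs, pmf = enum_pmf(k + l, k + m, k + l + m + n)
            point = pmf[list(xs).index(k)]
            p = fisher_exact(k, l, m, n, "two_sided_min_likelihood")
            assert point - 1e-12 <= p <= 1.0

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact(0, 0, 3, 5) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)


# ------------------------------------------------- conditional MLE odds ratio


class TestConditionalMle:
    def test_matches_grid_maximisation(self):
        for k, l, m, n in random_tables(25, max_margin=15, seed=4):
            est = conditional_mle_odds_ratio(k, l, m, n)
            oracle = grid_cmle(k, l, m, n)
            if est == 0 or math.isinf(est):
                assert oracle < 1e-6 or oracle > 1e6
            else:
                assert est == pytest.approx(oracle, rel=2e-3)

    def test_matches_scipy_conditional_estimator(self):
        for k, l, m, n in random_tables(200, seed=5):
            est = conditional_mle_odds_ratio(k, l, m, n)
            ref = scipy_odds_ratio([[k, l], [m, n]]).statistic
            if math.isinf(est):
                assert math.isinf(ref) or ref > 1e8
            else:
                assert est == pytest.approx(ref, rel=1e-6, abs=1e-10)

    def test_symmetric_table_gives_one(self):
        assert conditional_mle_odds_ratio(2, 2, 2, 2) == pytest.approx(1.0)

    def test_support_bounds(self):
        assert conditional_mle_odds_ratio(0, 5, 5, 10) == 0.0
        assert math.isinf(conditional_mle_odds_ratio(5, 0, 0, 10))

    def test_strictly_increasing_in_k_inside_support(self):
        row1, col1, total = 10, 12, 50
        lo = max(0, row1 + col1 - total)
        hi = min(row1, col1)
        ests = [
            conditional_mle_odds_ratio(
                k, row1 - k, col1 - k, total - row1 - col1 + k
            )
            for k in range(lo + 1, hi)
        ]
        assert all(a < b for a, b in zip(ests, ests[1:]))

    def test_differs_from_sample_odds_ratio_where_published_values_do(self):
        # the printed effect sizes follow the conditional-MLE convention,
        # which at 2 d.p. disagrees with the cross-product ratio here
        est = conditional_mle_odds_ratio(9, 5, 445, 2366)
        sample = sample_odds_ratio(9, 5, 445, 2366)
        assert round(est, 2) == 9.56
        assert round(sample, 2) == 9.57


# ------------------------------------------------------------ BY adjustment


class TestAdjustBy:
    def test_matches_statsmodels_when_family_equals_list(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40) ** 3
        ours = adjust_by(list(p))
        ref = multipletests(p, method="fdr_by")[1]
        assert np.allclose(ours, ref)

    def test_head_of_family_mode_reproduces_published_adjustment(self):
        # smallest 3 of a family of 1147 tests
        p = [2.09e-8, 4.92e-8, 2.64e-6]
        adj = adjust_by(p, total_tests=1147)
        c = sum(1 / i for i in range(1, 1148))
        assert adj[0] == pytest.approx(1147 * c * p[0] / 1, rel=1e-12)

    def test_all_ones_stay_ones(self):
        assert adjust_by([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_output_dominates_input_and_bh(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        by = np.array(adjust_by(list(p)))
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(by >= p - 1e-15)
        assert np.all(by >= bh - 1e-15)

    def test_order_preserved(self):
        p = [0.5, 0.001, 0.2]
        adj = adjust_by(p)
        assert adj[1] == min(adj)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            adjust_by([1.5])
        with pytest.raises(ValueError):
            adjust_by([0.1, 0.2], total_tests=1)


# ------------------------------------------------------- property checks


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    k=st.integers(0, 12),
    l=st.integers(0, 12),
    m=st.integers(0, 12),
    n=st.integers(0, 12),
)
def test_pvalues_in_unit_interval(k, l, m, n):
    for sided in ("greater", "two_sided_min_likelihood"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact(k, l, m, n, sided)
        assert 0 < p <= 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
def test_adjust_by_bounds_and_monotone_in_input(p):
    adj = adjust_by(p)
    assert all(0 <= a <= 1 for a in adj)
    assert all(a >= pi - 1e-15 for a, pi in zip(adj, p))
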