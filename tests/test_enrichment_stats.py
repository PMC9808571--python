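"""Exact-test kernels against independent oracles (Fractions, scipy, hand formulas)."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnaflow.enrichment_stats import (
    ContingencyTable,
    box_stats,
    chi_square_enrichment,
    fisher_exact_two_sided,
    hypergeom_pmf,
    spearman,
)


def fraction_pmf(a, b, c, d) -> Fraction:
    """Hypergeometric table probability via the exact factorial identity."""
    n = a + b + c + d
    return Fraction(
        math.factorial(a + b)
        * math.factorial(c + d)
        * math.factorial(a + c)
        * math.factorial(b + d),
        math.factorial(n)
        * math.factorial(a)
        * math.factorial(b)
        * math.factorial(c)
        * math.factorial(d),
    )


def fisher_oracle(a, b, c, d) -> float:
    """Independent sum-of-small-p enumeration in exact rational arithmetic."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    obs = fraction_pmf(a, b, c, d)
    total = Fraction(0)
    for k in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = fraction_pmf(k, row1 - k, col1 - k, n - col1 - (row1 - k))
        if p <= obs:
            total += p
    return float(min(total, Fraction(1)))


class TestHypergeomPmf:
    def test_direct_factorial_example(self):
        # C(7,7)*C(13,5)/C(20,12) = 1287/125970
        assert hypergeom_pmf(7, 12, 7, 20) == pytest.approx(1287 / 125970, rel=1e-12)

    def test_outside_support_is_zero(self):
        assert hypergeom_pmf(8, 12, 7, 20) == 0.0
        assert hypergeom_pmf(-1, 12, 7, 20) == 0.0

    def test_normalization(self):
        total = sum(hypergeom_pmf(k, 12, 7, 20) for k in range(0, 8))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy(self):
        for k in range(0, 8):
            assert hypergeom_pmf(k, 12, 7, 20) == pytest.approx(
                scipy.stats.hypergeom.pmf(k, 20, 7, 12), rel=1e-10
            )


class TestFisherExact:
    def test_printed_worked_example(self):
        # 5 initiator genes (0 eutherian) vs 7 target genes (5 eutherian)
        p = fisher_exact_two_sided(ContingencyTable(0, 5, 5, 2))
        assert p == pytest.approx(22 / 792, rel=1e-12)
        assert round(p, 3) == 0.028

    def test_symmetric_two_table_case(self):
        assert fisher_exact_two_sided(ContingencyTable(1, 0, 0, 1)) == 1.0

    def test_enumerated_example(self):
        # support sums to 125970; tables with pmf <= observed: k in {0,1,7}
        p = fisher_exact_two_sided(ContingencyTable(7, 5, 0, 8))
        assert p == pytest.approx(1846 / 125970, rel=1e-12)

    def test_all_zero_table_convention(self):
        assert fisher_exact_two_sided(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_against_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_transposition_invariance_and_range(self, cells):
        t = ContingencyTable(*cells)
        p = fisher_exact_two_sided(t)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_exact_two_sided(t.transpose()), rel=1e-12)

    def test_exhaustive_small_tables_match_rational_enumeration(self):
        # every table with grand total <= 16 (the N <= 30 sweep runs in the
        # acceptance suite)
        for n in range(0, 17):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        assert fisher_exact_two_sided(
                            ContingencyTable(a, b, c, d)
                        ) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-12)


class TestChiSquare:
    def test_equal_proportions_give_p_one(self):
        stat, p = chi_square_enrichment(10, 100, 20, 200)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        # 2x2: [[20, 80], [10, 890]]; statistic = sum (O-E)^2/E over 4 cells
        obs = np.array([[20, 80], [10, 890]], dtype=float)
        n = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        stat_hand = (((obs - exp) ** 2) / exp).sum()
        stat, p = chi_square_enrichment(20, 100, 10, 900)
        assert stat == pytest.approx(stat_hand, rel=1e-12)
        assert p == pytest.approx(scipy.stats.chi2.sf(stat_hand, 1), rel=1e-12)

    def test_matches_scipy_without_correction(self):
        stat, p = chi_square_enrichment(14, 14, 4, 40)
        ref = scipy.stats.chi2_contingency(
            [[14, 0], [4, 36]], correction=False
        )
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_row_swap_invariance(self):
        assert chi_square_enrichment(20, 100, 10, 900)[0] == pytest.approx(
            chi_square_enrichment(10, 900, 20, 100)[0]
        )

    def test_zero_expected_cell_advises_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_enrichment(0, 5, 0, 5)


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 2, n = 4 -> 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_absent(self):
        assert spearman([1, 1, 1], [1, 2, 3]) is None

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        ref = scipy.stats.spearmanr(x, y).statistic
        assert spearman(x, y) == pytest.approx(ref, rel=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(-100, 100), min_size=3, max_size=20, unique=True)
    )
    def test_invariant_under_monotone_transform(self, xs):
        ys = list(range(len(xs)))
        r1 = spearman(xs, ys)
        r2 = spearman(np.exp(np.asarray(xs, dtype=float) / 100.0), ys)  # monotone map
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert -1.0 <= r1 <= 1.0


class TestBoxStats:
    def test_one_to_nine_quartiles(self):
        bs = box_stats(range(1, 10))
        assert (bs.q1, bs.median, bs.q3) == (3.0, 5.0, 7.0)
        assert bs.outliers == []
        assert (bs.whisker_low, bs.whisker_high) == (1.0, 9.0)

    def test_extreme_value_flagged_as_outlier(self):
        bs = box_stats(list(range(1, 10)) + [100])
        assert 100.0 in bs.outliers
        assert bs.whisker_high < 100.0

    def test_single_value_degenerates(self):
        bs = box_stats([4.2])
        assert bs.q1 == bs.median == bs.q3 == 4.2
        assert bs.iqr == 0.0 and bs.outliers == []

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50))
    def test_invariants(self, values):
        bs = box_stats(values)
        assert bs.q1 <= bs.median <= bs.q3
        assert bs.whisker_low <= bs.median <= bs.whisker_high
        for o in bs.outliers:
            assert o > bs.q3 + 1.5 * bs.iqr or o < bs.q1 - 1.5 * bs.iqr
            assert o > bs.whisker_high or o < bs.whisker_low
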