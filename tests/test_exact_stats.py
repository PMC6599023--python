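"""Exact 2x2 and Hardy-Weinberg inference against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from quasimendel.exact_stats import (
    HweCounts,
    InvalidTableError,
    Table2x2,
    bonferroni_threshold,
    cmle_odds_ratio,
    exact_ci,
    fisher_test,
    fisher_two_sided,
    fold_enrichment,
    hwe_exact,
    hwe_excess_het,
    excess_het_phred,
)
from quasimendel.exact_stats import _pvals_for_margins, _upper_tail

from .oracles import (
    cmle_oracle,
    exact_ci_oracle,
    fisher_p_oracle,
    fisher_pvals_for_margins_oracle,
    hwe_p_oracle,
)

# strategy for valid random tables with n bounded
tables = (
    hst.tuples(hst.integers(0, 50), hst.integers(0, 50),
               hst.integers(0, 50), hst.integers(0, 50))
    .filter(lambda q: q[0] + q[1] > 0 and q[2] + q[3] > 0)
    .map(lambda q: Table2x2(*q))
)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected, places",
        [
            # published patients-vs-controls allele table
            ((14, 648, 148, 24610), 9.2e-5, None),
            # symmetric identical rows
            ((1, 9, 1, 9), 1.0, 12),
            # full enumeration over a in {0, 1, 2}: 2 * 45/190
            ((2, 8, 0, 10), 2 * 45 / 190, 10),
        ],
    )
    def test_known_values(self, table, expected, places):
        p = fisher_two_sided(Table2x2(*table))
        if places is None:  # printed precision: 2 significant figures
            assert f"{p:.1e}" == f"{expected:.1e}"
        else:
            assert p == pytest.approx(expected, abs=10 ** -places)

    def test_exhaustive_enumeration_small_n(self):
        """Margin sweep up to n = 25: every possible table matches the
        exact rational oracle (the acceptance suite extends this to 60)."""
        for n in range(2, 26):
            for r1 in range(1, n):
                r2 = n - r1
                for m in range(0, n + 1):
                    mine = _pvals_for_margins(r1, r2, m)[1]
                    ref = fisher_pvals_for_margins_oracle(r1, r2, m)
                    assert np.allclose(mine, [float(x) for x in ref], rtol=1e-9)

    @given(tables)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_scipy_cross_implementation(self, t):
        expected = st.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
        assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-8, abs=1e-12)

    @given(tables)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_row_and_column_swap_invariance(self, t):
        swapped = Table2x2(t.d, t.c, t.b, t.a)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(swapped), rel=1e-10
        )

    def test_degenerate_tables_give_one(self):
        assert fisher_two_sided(Table2x2(0, 5, 0, 7)) == 1.0
        assert fisher_two_sided(Table2x2(5, 0, 7, 0)) == 1.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(InvalidTableError):
            Table2x2(-1, 2, 3, 4)
        with pytest.raises(InvalidTableError):
            Table2x2(0, 0, 3, 4)

    def test_upper_tail_monotone_in_a(self):
        """With b, c, d fixed, growing a weakly decreases P(A >= a)."""
        b, c, d = 17, 5, 40
        tails = [_upper_tail(Table2x2(a, b, c, d), 0.0) for a in range(0, 12)]
        assert all(x >= y - 1e-12 for x, y in zip(tails, tails[1:]))


class TestCmleOddsRatio:
    def test_published_example(self):
        est, defined = cmle_odds_ratio(Table2x2(6, 716, 148, 24610))
        assert defined and f"{est:.1f}" == "1.4"

    @pytest.mark.parametrize("table", [(7, 49, 121, 6987), (3, 9, 4, 20), (12, 88, 31, 69)])
    def test_matches_grid_maximisation_oracle(self, table):
        est, _ = cmle_odds_ratio(Table2x2(*table))
        assert est == pytest.approx(cmle_oracle(*table), rel=1e-4)

    @given(tables)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_scipy_conditional_mle(self, t):
        est, defined = cmle_odds_ratio(t)
        if not defined:
            return
        ref = scipy_odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional").statistic
        if math.isinf(est) or est == 0.0:
            assert math.isinf(ref) or ref == 0.0 or ref != ref
        else:
            assert est == pytest.approx(ref, rel=1e-4)

    def test_support_boundaries(self):
        assert cmle_odds_ratio(Table2x2(0, 10, 5, 5)) == (0.0, True)
        assert cmle_odds_ratio(Table2x2(10, 0, 5, 5))[0] == math.inf
        est, defined = cmle_odds_ratio(Table2x2(0, 5, 0, 7))
        assert not defined


class TestExactCi:
    def test_published_example(self):
        lo, hi = exact_ci(Table2x2(6, 716, 148, 24610))
        assert f"{lo:.2f}" == "0.50"
        assert hi == pytest.approx(3.12, abs=0.01)

    def test_zero_cell_boundary(self):
        lo, hi = exact_ci(Table2x2(0, 10, 5, 5))
        assert lo == 0.0 and hi < math.inf

    @pytest.mark.parametrize("table", [(2, 8, 0, 10), (5, 15, 9, 31), (1, 12, 7, 18)])
    def test_matches_tail_enumeration_oracle(self, table):
        lo, hi = exact_ci(Table2x2(*table))
        ref_lo, ref_hi = exact_ci_oracle(*table)
        assert lo == pytest.approx(ref_lo, abs=1e-3, rel=1e-3)
        if math.isinf(hi):
            assert math.isinf(ref_hi)
        else:
            assert hi == pytest.approx(ref_hi, abs=1e-3, rel=1e-3)

    @given(tables)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_brackets_cmle_estimate(self, t):
        est, defined = cmle_odds_ratio(t)
        if not defined or est == 0.0 or math.isinf(est):
            return
        lo, hi = exact_ci(t)
        assert lo - 1e-9 <= est <= hi + 1e-9

    def test_level_validation(self):
        with pytest.raises(InvalidTableError):
            exact_ci(Table2x2(1, 2, 3, 4), level=1.5)

    def test_bundle_consistency(self):
        res = fisher_test(Table2x2(5, 15, 9, 31))
        assert res.ci_low <= res.or_cmle <= res.ci_high
        assert 0 <= res.p_two_sided <= 1


class TestHweExact:
    def test_monomorphic_site_is_one(self):
        assert hwe_exact(HweCounts(17, 0, 0)) == 1.0
        assert hwe_exact(HweCounts(0, 0, 9)) == 1.0

    @pytest.mark.parametrize(
        "counts", [(9, 2, 1), (5, 5, 2), (40, 12, 3), (3, 3, 3)]
    )
    def test_matches_rational_enumeration_oracle(self, counts):
        assert hwe_exact(HweCounts(*counts)) == pytest.approx(
            float(hwe_p_oracle(*counts)), rel=1e-9
        )

    def test_perfect_hwe_proportions_near_one(self):
        assert hwe_exact(HweCounts(25, 50, 25)) >= 0.99

    def test_super_uniform_under_null(self, rng):
        """P(p <= alpha) <= alpha + discreteness slack when genotypes are
        drawn under Hardy-Weinberg equilibrium."""
        n, sites = 80, 2000
        qs = rng.uniform(0.05, 0.5, sites)
        pvals = []
        for q in qs:
            g = rng.binomial(2, q, n)
            pvals.append(
                hwe_exact(HweCounts(int((g == 0).sum()), int((g == 1).sum()),
                                    int((g == 2).sum())))
            )
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05):
            rate = (pvals <= alpha).mean()
            slack = 3 * math.sqrt(alpha * (1 - alpha) / sites)
            assert rate <= alpha + slack

    def test_excess_het_tail_and_phred(self):
        # 50 hets and no homozygotes: far more heterozygous than HWE allows
        g = HweCounts(0, 50, 0)
        assert hwe_excess_het(g) < 1e-3
        assert excess_het_phred(g) > 20
        # balanced counts: unremarkable phred score
        assert excess_het_phred(HweCounts(25, 50, 25)) < 20


class TestScalarHelpers:
    def test_fold_enrichment_published(self):
        assert f"{fold_enrichment(14 / 662, 148 / 24758):.1f}" == "3.5"

    def test_fold_enrichment_edges(self):
        assert fold_enrichment(0.37, 0.37) == 1.0
        assert fold_enrichment(0.0, 0.2) == 0.0
        with pytest.raises(ZeroDivisionError):
            fold_enrichment(0.1, 0.0)

    def test_bonferroni_threshold(self):
        assert f"{bonferroni_threshold(0.05, 178):.2e}" == "2.81e-04"
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
        with pytest.raises(InvalidTableError):
            bonferroni_threshold(0.05, 0)
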