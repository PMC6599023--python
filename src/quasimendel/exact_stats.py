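"""Exact inference on 2x2 allele-count tables and Hardy-Weinberg genotype counts.

This is the statistical core of the package.  All tests condition on the
observed margins of the table:

* the two-sided Fisher p-value sums, under the central hypergeometric null,
  the probabilities of every table (with the same margins) whose point
  probability does not exceed that of the observed table — the convention of
  R's ``fisher.test``;
* the odds-ratio estimate is the conditional MLE (CMLE) under Fisher's
  noncentral hypergeometric likelihood, found by solving
  ``E_psi[A] = a`` by bisection on the log odds ratio;
* the exact confidence interval inverts the two one-sided noncentral tail
  tests at ``(1 - level)/2`` each.

The Hardy-Weinberg exact test enumerates, at fixed allele counts, every
heterozygote count of matching parity and sums the probabilities that do not
exceed the observed configuration's (the Wigginton-Cutler-Abecasis test).
A one-sided heterozygote-excess tail is exposed separately because the GATK
``ExcessHet`` annotation is its phred-scaled form.

All hypergeometric terms are computed through log-gamma, so counts in the
tens of thousands (the cohort sizes used here) are exact to double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "Table2x2",
    "FisherResult",
    "HweCounts",
    "fisher_two_sided",
    "cmle_odds_ratio",
    "exact_ci",
    "fisher_test",
    "hwe_exact",
    "hwe_excess_het",
    "excess_het_phred",
    "fold_enrichment",
    "bonferroni_threshold",
]

#: Relative tolerance used when comparing point probabilities, guarding
#: against float ties in "probability <= observed probability" sums.
REL_TOL = 1e-7

#: Bisection bracket for the log odds ratio (natural-log units).
_LOG_PSI_BRACKET = 30.0


class InvalidTableError(ValueError):
    """Raised for tables or genotype counts violating their invariants."""


@dataclass(frozen=True)
class Table2x2:
    """Allele-count contingency table.

    ``a``/``b`` are the alt/ref allele counts in group 1 (e.g. patients),
    ``c``/``d`` the alt/ref counts in group 2 (e.g. controls).  Both groups
    must be non-empty; counts are non-negative integers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidTableError(f"count {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise InvalidTableError("each group must contain at least one allele")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col_alt(self) -> int:
        return self.a + self.c

    @property
    def col_ref(self) -> int:
        return self.b + self.d

    def swapped(self) -> "Table2x2":
        """The table with the two groups exchanged (OR inverts)."""
        return Table2x2(self.c, self.d, self.a, self.b)

    @property
    def degenerate(self) -> bool:
        """True when one allele column is empty: only one table fits the margins."""
        return self.col_alt == 0 or self.col_ref == 0


@dataclass(frozen=True)
class FisherResult:
    """Exact test result: two-sided p, CMLE odds ratio and exact CI."""

    p_two_sided: float
    or_cmle: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    or_defined: bool = True


@dataclass(frozen=True)
class HweCounts:
    """Genotype counts at one biallelic site."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidTableError(f"{name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise InvalidTableError("at least one genotyped individual required")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_hom_alt + self.n_het


# ---------------------------------------------------------------------------
# hypergeometric machinery (conditioning on all margins of a 2x2 table)
# ---------------------------------------------------------------------------

def _support(t: Table2x2) -> np.ndarray:
    """All values the a-cell can take given the margins."""
    lo = max(0, t.col_alt - t.row2)
    hi = min(t.row1, t.col_alt)
    return np.arange(lo, hi + 1)


def _log_comb(n: int | np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_weights(t: Table2x2, ks: np.ndarray) -> np.ndarray:
    """log of C(row1, k) * C(row2, col_alt - k) over the support."""
    return _log_comb(t.row1, ks) + _log_comb(t.row2, t.col_alt - ks)


def _conditional_pmf(t: Table2x2, log_psi: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the (non)central hypergeometric at log odds ratio."""
    ks = _support(t)
    lw = _log_weights(t, ks) + log_psi * ks
    return ks, np.exp(lw - logsumexp(lw))


def _pvals_for_margins(row1: int, row2: int, col_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and two-sided Fisher p for every a consistent with the margins.

    Entry i of the second array is the p-value of the table whose a-cell equals
    ``support[i]``; exhaustive tests sweep margins through this helper.
    """
    lo = max(0, col_alt - row2)
    hi = min(row1, col_alt)
    ks = np.arange(lo, hi + 1)
    lw = _log_comb(row1, ks) + _log_comb(row2, col_alt - ks)
    pmf = np.exp(lw - logsumexp(lw))
    pvals = np.array(
        [min(1.0, float(pmf[pmf <= p_obs * (1.0 + REL_TOL)].sum())) for p_obs in pmf]
    )
    return ks, pvals


def fisher_two_sided(t: Table2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule."""
    if t.degenerate:
        return 1.0
    ks, pmf = _conditional_pmf(t)
    p_obs = float(pmf[ks == t.a][0])
    return min(1.0, float(pmf[pmf <= p_obs * (1.0 + REL_TOL)].sum()))


def _conditional_mean(t: Table2x2, log_psi: float) -> float:
    ks, pmf = _conditional_pmf(t, log_psi)
    return float(np.dot(ks, pmf))


def cmle_odds_ratio(t: Table2x2) -> tuple[float, bool]:
    """Conditional-MLE odds ratio; returns ``(estimate, defined)``.

    At the support boundaries the likelihood is maximised at 0 (``a`` at its
    minimum) or +inf (``a`` at its maximum); a degenerate table (empty alt or
    ref column) admits a single configuration and the estimate is undefined.
    """
    if t.degenerate:
        return math.nan, False
    ks = _support(t)
    if ks.size == 1:
        return math.nan, False
    if t.a == ks[0]:
        return 0.0, True
    if t.a == ks[-1]:
        return math.inf, True
    lo, hi = -_LOG_PSI_BRACKET, _LOG_PSI_BRACKET
    # E_psi[A] is strictly increasing in psi; bisect E - a = 0 on log psi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        diff = _conditional_mean(t, mid) - t.a
        if abs(diff) < 1e-8 and hi - lo < 1e-10:
            break
        if diff < 0:
            lo = mid
        else:
            hi = mid
    return math.exp(0.5 * (lo + hi)), True


def _upper_tail(t: Table2x2, log_psi: float) -> float:
    """P_psi(A >= a_observed)."""
    ks, pmf = _conditional_pmf(t, log_psi)
    return float(pmf[ks >= t.a].sum())


def _lower_tail(t: Table2x2, log_psi: float) -> float:
    """P_psi(A <= a_observed)."""
    ks, pmf = _conditional_pmf(t, log_psi)
    return float(pmf[ks <= t.a].sum())


def _solve_monotone(f, target: float, increasing: bool) -> float:
    """Bisection for f(log_psi) = target on the standard bracket."""
    lo, hi = -_LOG_PSI_BRACKET, _LOG_PSI_BRACKET
    f_lo, f_hi = f(lo), f(hi)
    if increasing:
        if f_lo >= target:
            return lo
        if f_hi <= target:
            return hi
    else:
        if f_lo <= target:
            return lo
        if f_hi >= target:
            return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if (val < target) == increasing:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


def exact_ci(t: Table2x2, level: float = 0.95) -> tuple[float, float]:
    """Exact CI for the odds ratio by inverting one-sided noncentral tails."""
    if not (0.0 < level < 1.0):
        raise InvalidTableError(f"confidence level must lie in (0, 1), got {level}")
    if t.degenerate:
        return 0.0, math.inf
    alpha = (1.0 - level) / 2.0
    ks = _support(t)
    if ks.size == 1:
        return 0.0, math.inf
    if t.a == ks[0]:
        low = 0.0
    else:
        # upper tail P(A >= a) increases with psi
        low = math.exp(_solve_monotone(lambda lp: _upper_tail(t, lp), alpha, increasing=True))
    if t.a == ks[-1]:
        high = math.inf
    else:
        high = math.exp(_solve_monotone(lambda lp: _lower_tail(t, lp), alpha, increasing=False))
    return low, high


def fisher_test(t: Table2x2, level: float = 0.95) -> FisherResult:
    """Convenience bundle: two-sided p, CMLE OR and exact CI at ``level``."""
    p = fisher_two_sided(t)
    est, defined = cmle_odds_ratio(t)
    lo, hi = exact_ci(t, level)
    return FisherResult(p, est, lo, hi, level, defined)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_distribution(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Support (het counts) and exact pmf of heterozygote count at fixed alleles.

    P(het | n, n_alt) ∝ n! / (hom_ref! het! hom_alt!) * 2^het with
    hom_alt = (n_alt - het)/2; het runs over values of n_alt's parity.
    """
    het_max = min(n_alt, 2 * n - n_alt)
    hets = np.arange(n_alt % 2, het_max + 1, 2)
    hom_alt = (n_alt - hets) // 2
    hom_ref = n - hets - hom_alt
    lw = (
        gammaln(n + 1)
        - gammaln(hom_ref + 1)
        - gammaln(hets + 1)
        - gammaln(hom_alt + 1)
        + hets * math.log(2.0)
    )
    return hets, np.exp(lw - logsumexp(lw))


def hwe_exact(g: HweCounts) -> float:
    """Two-sided exact Hardy-Weinberg p-value at fixed allele counts."""
    n, n_alt = g.n, g.n_alt_alleles
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0  # monomorphic: single configuration
    hets, pmf = _hwe_distribution(n, n_alt)
    p_obs = float(pmf[hets == g.n_het][0])
    return min(1.0, float(pmf[pmf <= p_obs * (1.0 + REL_TOL)].sum()))


def hwe_excess_het(g: HweCounts) -> float:
    """One-sided heterozygote-excess tail: P(het >= observed)."""
    n, n_alt = g.n, g.n_alt_alleles
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0
    hets, pmf = _hwe_distribution(n, n_alt)
    return min(1.0, float(pmf[hets >= g.n_het].sum()))


def excess_het_phred(g: HweCounts) -> float:
    """Phred-scaled heterozygote excess, the GATK ``ExcessHet`` convention."""
    p = hwe_excess_het(g)
    return -10.0 * math.log10(max(p, 1e-300))


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def fold_enrichment(freq_a: float, freq_b: float) -> float:
    """Ratio of two frequencies (e.g. case over control allele frequency)."""
    if freq_b == 0:
        raise ZeroDivisionError("fold enrichment undefined for zero reference frequency")
    return freq_a / freq_b


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise InvalidTableError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests
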