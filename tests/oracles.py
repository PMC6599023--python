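"""Independent brute-force oracles for the exact-inference tests.

Everything here is deliberately naive: exact rational arithmetic or direct
enumeration/maximisation, sharing no code path with the package's
implementations beyond the table type.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial, inf, log

import numpy as np
from scipy.special import gammaln


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact rational enumeration of all tables."""
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    weights = {k: comb(r1, k) * comb(r2, m - k) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    acc = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(acc, total)


def fisher_pvals_for_margins_oracle(r1: int, r2: int, m: int) -> list[Fraction]:
    """p for every a in the support of the margins, exact rationals."""
    lo, hi = max(0, m - r2), min(r1, m)
    weights = [comb(r1, k) * comb(r2, m - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    return [
        Fraction(sum(w for w in weights if w <= w_obs), total) for w_obs in weights
    ]


def _cond_loglik(a, r1, r2, m, log_psi: float) -> float:
    lo, hi = max(0, m - r2), min(r1, m)
    ks = np.arange(lo, hi + 1)
    lw = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(m - ks + 1) - gammaln(r2 - m + ks + 1)
        + ks * log_psi
    )
    mx = lw.max()
    denom = mx + log(np.exp(lw - mx).sum())
    obs = lw[ks == a][0]
    return float(obs - denom)


def cmle_oracle(a: int, b: int, c: int, d: int) -> float:
    """Conditional-likelihood maximisation by grid + golden-section refine."""
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    if a == lo:
        return 0.0
    if a == hi:
        return inf
    grid = np.linspace(-25, 25, 2001)
    lls = [_cond_loglik(a, r1, r2, m, lp) for lp in grid]
    i = int(np.argmax(lls))
    x_lo, x_hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    phi = (np.sqrt(5) - 1) / 2
    for _ in range(80):
        x1 = x_hi - phi * (x_hi - x_lo)
        x2 = x_lo + phi * (x_hi - x_lo)
        if _cond_loglik(a, r1, r2, m, x1) < _cond_loglik(a, r1, r2, m, x2):
            x_lo = x1
        else:
            x_hi = x2
    return float(np.exp(0.5 * (x_lo + x_hi)))


def _tails(a, r1, r2, m, psi: float) -> tuple[float, float]:
    """(P(A >= a), P(A <= a)) at odds ratio psi, exact combinatorial weights."""
    lo, hi = max(0, m - r2), min(r1, m)
    ws = [comb(r1, k) * comb(r2, m - k) * psi ** (k - lo) for k in range(lo, hi + 1)]
    total = sum(ws)
    upper = sum(w for k, w in zip(range(lo, hi + 1), ws) if k >= a) / total
    lower = sum(w for k, w in zip(range(lo, hi + 1), ws) if k <= a) / total
    return upper, lower


def exact_ci_oracle(a: int, b: int, c: int, d: int, level: float = 0.95):
    """CI bounds by bisection on psi of the enumerated tail functions."""
    r1, r2, m = a + b, c + d, a + c
    lo_s, hi_s = max(0, m - r2), min(r1, m)
    alpha = (1 - level) / 2

    def bisect(f, target, increasing, lo=1e-12, hi=1e12):
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if (f(mid) < target) == increasing:
                lo = mid
            else:
                hi = mid
        return float(np.sqrt(lo * hi))

    low = 0.0 if a == lo_s else bisect(
        lambda psi: _tails(a, r1, r2, m, psi)[0], alpha, increasing=True
    )
    high = inf if a == hi_s else bisect(
        lambda psi: _tails(a, r1, r2, m, psi)[1], alpha, increasing=False
    )
    return low, high


def hwe_p_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact HWE p by rational enumeration over heterozygote counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    if n_alt == 0 or n_alt == 2 * n:
        return Fraction(1)
    weights = {}
    for het in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        hom_alt = (n_alt - het) // 2
        hom_ref = n - het - hom_alt
        # multinomial coefficient times 2^het
        w = (
            Fraction(
                factorial(n),
                factorial(hom_ref) * factorial(het) * factorial(hom_alt),
            )
            * 2**het
        )
        weights[het] = w
    total = sum(weights.values())
    w_obs = weights[n_het]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)
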