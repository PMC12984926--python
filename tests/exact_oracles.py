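"""Independent brute-force oracles used to check the package's statistics.

Everything here is exact integer/rational arithmetic built directly from
the defining formulas, deliberately sharing no code with the
implementations under test.
"""

from __future__ import annotations

import bisect
from fractions import Fraction
from math import comb


def fet_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration, as an exact Fraction.

    Every admissible table with the observed margins is enumerated; the
    point probability of the table with first cell k is
    C(r1, k) * C(r2, c1 - k) / C(n, c1), so probability comparisons reduce
    to exact integer comparisons of the binomial weights.
    """
    n = a + b + c + d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(total, comb(n, c1))


def hypergeom_upper_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct mass summation."""
    total = sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )
    return Fraction(total, comb(N, n))


class _MarginTable:
    """Pre-sorted binomial weights for one margin set; fast per-cell p lookup."""

    def __init__(self, n: int, r1: int, c1: int):
        r2 = n - r1
        lo, hi = max(0, c1 - r2), min(r1, c1)
        self.lo = lo
        self.weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
        self.sorted_weights = sorted(self.weights)
        self.prefix = [0]
        for w in self.sorted_weights:
            self.prefix.append(self.prefix[-1] + w)
        self.denom = comb(n, c1)

    def p_two_sided(self, a: int) -> Fraction:
        w_obs = self.weights[a - self.lo]
        idx = bisect.bisect_right(self.sorted_weights, w_obs)
        return Fraction(self.prefix[idx], self.denom)


def sweep_all_tables(max_n: int):
    """Yield (a, b, c, d, exact_p) for every 2x2 table with 1 <= n <= max_n."""
    for n in range(1, max_n + 1):
        for r1 in range(0, n + 1):
            for c1 in range(0, n + 1):
                margin = _MarginTable(n, r1, c1)
                r2 = n - r1
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    b = r1 - a
                    c = c1 - a
                    d = r2 - c
                    yield a, b, c, d, margin.p_two_sided(a)
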