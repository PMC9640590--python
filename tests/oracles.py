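"""Independent reference implementations used to cross-check the package.

These deliberately use brute force and exact rational arithmetic, not the
code paths they validate.
"""

from fractions import Fraction
from math import factorial


def fisher_two_sided_exact(a, b, c, d, rel_tol=1e-7):
    """Two-sided Fisher p by exhaustive enumeration of all 2x2 tables with
    the observed margins, in exact rational arithmetic.

    Point probability of a table: (a+b)!(c+d)!(a+c)!(b+d)! / (m!a!b!c!d!).
    The p-value sums point probabilities not exceeding the observed one,
    with a small relative tolerance on the comparison.
    """
    m = a + b + c + d
    if m == 0 or a + b == 0 or c + d == 0:
        return 1.0

    def psi(aa):
        bb, cc, dd = (a + b) - aa, (a + c) - aa, d - a + aa
        num = (factorial(a + b) * factorial(c + d)
               * factorial(a + c) * factorial(b + d))
        den = (factorial(m) * factorial(aa) * factorial(bb)
               * factorial(cc) * factorial(dd))
        return Fraction(num, den)

    psi_obs = psi(a)
    cutoff = psi_obs * (Fraction(1) + Fraction(rel_tol).limit_denominator(10**12))
    lo = max(0, a - d)
    hi = min(a + b, a + c)
    total = sum(psi(aa) for aa in range(lo, hi + 1) if psi(aa) <= cutoff)
    return float(total)


def bh_step_up(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule:
    sort ascending, multiply by m/rank, take the cumulative minimum from
    the largest rank down, clip at 1, restore input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running_min = min(running_min, pvals[idx] * m / rank)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted
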