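"""Independent brute-force oracles used to check the package's results.

Each oracle is written from the mathematical definition, independent of the
implementation path it checks (and of the libraries that path uses).
"""

from __future__ import annotations

import math
from fractions import Fraction

NEG = float("-inf")


def affine_dp_score(a: str, b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Optimal global affine-gap alignment score by a three-state DP.

    gap_open is the score of a gap's first residue, gap_extend of each
    subsequent one; end gaps are charged like any other.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_alignments_score(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Optimal score by exhaustive enumeration of every gapped alignment.

    Exponential; only usable for very short sequences.  Validates the DP
    oracle itself.
    """
    best = [NEG]

    def rec(i, j, state, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "X", score + (gap_extend if state == "X" else gap_open))
        if j < len(b):
            rec(i, j + 1, "Y", score + (gap_extend if state == "Y" else gap_open))

    rec(0, 0, "start", 0.0)
    return best[0]


def score_alignment_rows(row_a: str, row_b: str, match, mismatch, gap_open, gap_extend):
    """Score an explicit pair of gapped rows under the affine model."""
    score, state = 0.0, "M"
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            raise ValueError("double-gap column")
        if x == "-":
            score += gap_extend if state == "Y" else gap_open
            state = "Y"
        elif y == "-":
            score += gap_extend if state == "X" else gap_open
            state = "X"
        else:
            score += match if x == y else mismatch
            state = "M"
    return score


def fisher_enumerate(table, alternative: str) -> Fraction:
    """Exact Fisher p by full hypergeometric enumeration (exact rationals).

    Tables share the observed margins; one-sided alternatives sum the tail
    in the [0][0] cell, two_sided sums tables with point probability <= the
    observed one (exact integer comparison, same denominator throughout).
    """
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)

    def weight(x):  # numerator of P(X = x); common denominator C(n, c1)
        return math.comb(r1, x) * math.comb(n - r1, c1 - x)

    denom = math.comb(n, c1)
    if alternative == "greater":
        num = sum(weight(x) for x in range(a, hi + 1))
    elif alternative == "less":
        num = sum(weight(x) for x in range(lo, a + 1))
    else:
        wa = weight(a)
        num = sum(w for x in range(lo, hi + 1) if (w := weight(x)) <= wa)
    return Fraction(num, denom)


def pearson_chi_square(table):
    """Chi-square statistic from first principles (margins -> expecteds)."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = rows[i] * cols[j] / total
            stat += (obs - exp) ** 2 / exp
    return stat


def n50_brute(lengths):
    """Smallest L whose >=L contigs cover half the assembly, by direct scan
    over candidate lengths."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths)):
        if sum(x for x in lengths if x >= L) >= total / 2:
            best = L
    return best


def jc_numerical_inverse(p: float, tol: float = 1e-14) -> float:
    """Invert the JC expected-p curve p(K) = (3/4)(1 - e^{-4K/3}) by
    bisection, independent of the closed-form correction."""
    lo, hi = 0.0, 60.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if 0.75 * (1 - math.exp(-4 * mid / 3)) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2
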