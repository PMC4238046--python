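"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain step-by-step Python (loops, exact
fractions) so it shares no code path with the package: Z-scoring, the
Z-ratio statistic, the equal-variance t-test (statistic by hand, tail from
the t distribution function), the exact hypergeometric tail, and the
exclusive/shared set partition.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy.stats import t as t_dist  # distribution function only


def zscore_columns(matrix: list[list[float]]) -> list[list[float]]:
    """Population-SD Z-scores per column of a genes x samples list matrix."""
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    out = [[0.0] * n_cols for _ in range(n_rows)]
    for j in range(n_cols):
        col = [matrix[i][j] for i in range(n_rows)]
        mu = sum(col) / n_rows
        sd = math.sqrt(sum((x - mu) ** 2 for x in col) / n_rows)
        for i in range(n_rows):
            out[i][j] = (matrix[i][j] - mu) / sd
    return out


def z_ratios(matrix: list[list[float]], test_cols: list[int], ref_cols: list[int]) -> list[float]:
    """Z-ratios computed step by step from a raw intensity matrix."""
    z = zscore_columns(matrix)
    diffs = []
    for row in z:
        mt = sum(row[j] for j in test_cols) / len(test_cols)
        mr = sum(row[j] for j in ref_cols) / len(ref_cols)
        diffs.append(mt - mr)
    mu = sum(diffs) / len(diffs)
    sd = math.sqrt(sum((d - mu) ** 2 for d in diffs) / len(diffs))
    return [d / sd for d in diffs]


def t_test_pvalue(a: list[float], b: list[float]) -> float:
    """Equal-variance two-sample two-tailed t-test, statistic by hand."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0:
        return 1.0 if ma == mb else 0.0
    t_stat = (ma - mb) / se
    return 2.0 * float(t_dist.sf(abs(t_stat), df))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n) via fraction sums."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


def partition_sets(
    universe: set[str], sig_tl: set[str], sig_tr: set[str]
) -> dict[str, set[str]]:
    """Exclusive/shared/null partition by direct set algebra."""
    return {
        "exclusive_tl": (sig_tl - sig_tr) & universe,
        "exclusive_tr": (sig_tr - sig_tl) & universe,
        "shared": sig_tl & sig_tr & universe,
        "null": universe - sig_tl - sig_tr,
    }
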