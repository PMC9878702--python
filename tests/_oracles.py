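"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid scipy and the package's own code paths:
hypergeometric and Fisher probabilities are exact rationals from
binomial coefficients, BH is the literal two-pass step-up definition,
and TOM is a triple loop over the formula.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_pmf_exact(N: int, K: int, n: int):
    """Exact pmf over the attainable support, as Fractions."""
    lo, hi = max(0, n + K - N), min(n, K)
    denom = comb(N, n)
    return {k: Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(lo, hi + 1)}


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    pmf = hypergeom_pmf_exact(N, K, n)
    return sum((p for kk, p in pmf.items() if kk >= k), Fraction(0))


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Point-probability two-sided Fisher p by full enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    pmf = hypergeom_pmf_exact(N, r1, c1)  # distribution of cell a
    observed = pmf[a]
    return sum((p for p in pmf.values() if p <= observed), Fraction(0))


def bh_reference(pvalues):
    """Literal two-pass Benjamini-Hochberg step-up."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def tom_brute_force(adjacency: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom
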