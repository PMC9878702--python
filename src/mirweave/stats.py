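"""Exact small-sample statistics shared by every pipeline stage.

All enrichment stages reduce to two exact tests — the hypergeometric
upper tail for overlap of a fixed gene list with a fixed target set, and
Fisher's exact test for 2x2 association — plus Benjamini-Hochberg
adjustment across whatever family of tests a stage runs. They are
collected here so each stage tests against a single, well-audited
surface.

Conventions
-----------
* ``hypergeometric_tail`` returns ``P(X >= k)`` (enrichment direction).
* ``fisher_exact_two_sided`` uses the point-probability rule: the
  two-sided p-value is the total probability of all tables with the
  same margins whose point probability does not exceed the observed
  table's (within a small relative tolerance).
* ``bh_adjust`` is the classic step-up procedure, clipped to 1,
  returned in input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


@dataclass(frozen=True)
class HypergeomQuery:
    """Parameters of a hypergeometric overlap question.

    Attributes
    ----------
    N : int
        Universe size (e.g. genes measured and present in the compendium).
    K : int
        Successes in the universe (e.g. predicted targets of one miRNA).
    n : int
        Draws (e.g. differentially expressed genes of one direction).
    k : int
        Observed overlap between the draw and the success set.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        N, K, n, k = self.N, self.K, self.n, self.k
        if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
            raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
        lo, hi = max(0, n + K - N), min(n, K)
        if not (lo <= k <= hi):
            raise ValueError(f"overlap k={k} outside attainable range [{lo}, {hi}]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; row 1 = condition present, column 1 = outcome present."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table cells must be non-negative")

    def odds_ratio(self) -> float:
        """Sample odds ratio ad/bc; inf when bc == 0 and ad > 0, nan for 0/0."""
        num = self.a * self.d
        den = self.b * self.c
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den


def hypergeometric_tail(q: HypergeomQuery) -> float:
    """Upper-tail probability ``P(X >= k)`` for X ~ Hypergeom(N, K, n).

    Evaluated in log space (via the log-gamma expansion of the
    hypergeometric pmf) so it stays finite for universes of tens of
    thousands of genes.
    """
    if q.k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates terms via gammaln internally.
    p = float(_sps.hypergeom.sf(q.k - 1, q.N, q.K, q.n))
    return min(max(p, 0.0), 1.0)


def fisher_exact_two_sided(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, pvalue)`` where the odds ratio is the sample
    odds ratio ``ad/bc`` and the p-value sums the probabilities of all
    tables with the observed margins whose point probability is at most
    the observed one (point-probability rule).
    """
    res = _sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return t.odds_ratio(), float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]
        Raw p-values of one test family.

    Returns
    -------
    numpy.ndarray
        Adjusted values ``q_i = min_{j: p_(j) >= p_(i)} m p_(j) / j``
        clipped to 1, aligned with the input positions. Ties are
        resolved by input order, which cannot change the adjusted
        values (equal raw p share an adjusted value).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires at least one p-value")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value.

    The p-value comes from ``t = r sqrt((n-2) / (1-r^2))`` on ``n-2``
    degrees of freedom. Requires length >= 3 and nonzero variance in
    both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = _sps.pearsonr(x, y)
    return float(r), float(p)


def pooled_t_ci(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Pooled-variance two-sample CI for ``mean1 - mean2``.

    Uses the classical equal-variance Student interval with
    ``df = n1 + n2 - 2``, the textbook companion of the two-sample
    pooled t-test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tcrit = float(_sps.t.ppf(0.5 + level / 2.0, df))
    diff = mean1 - mean2
    return diff - tcrit * se, diff + tcrit * se


def pooled_t_test(n1, mean1, sd1, n2, mean2, sd2) -> tuple[float, float]:
    """Two-sided pooled-variance t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    tstat = (mean1 - mean2) / se
    p = 2.0 * float(_sps.t.sf(abs(tstat), df))
    return float(tstat), p


def zscore_rows(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each row to mean 0, sample sd 1 (denominator n-1).

    Returns ``(zmatrix, kept_mask)`` where constant rows are excluded
    from ``zmatrix`` and flagged False in ``kept_mask`` rather than
    silently zeroed.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    sd = m.std(axis=1, ddof=1)
    kept = sd > 0
    z = (m[kept] - m[kept].mean(axis=1, keepdims=True)) / sd[kept, None]
    return z, kept
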