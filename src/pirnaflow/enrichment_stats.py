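"""Exact and rank statistics used throughout the pipeline.

Fisher's exact test here follows the two-sided *sum-of-small-p* convention:
the p-value is the total probability, over all 2x2 tables with the observed
margins, of every table whose hypergeometric probability does not exceed
that of the observed table.  This is the convention of R's ``fisher.test``
and is implemented with exact integer arithmetic (binomial-coefficient
numerators over the common denominator), so probability ties are handled
exactly rather than to a floating-point tolerance.

The hypergeometric pmf is exposed separately and computed in log space so
it stays finite for large margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as _chi2
from scipy.stats import rankdata


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table: rows are gene sets, columns trait present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"cells must be non-negative integers, got {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass
class BoxStats:
    """Box-plot summary with the 1.5 x IQR outlier rule.

    Outliers are values strictly above Q3 + 1.5*IQR or strictly below
    Q1 - 1.5*IQR; whiskers sit at the most extreme non-outlier values.
    """

    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(k: int, row1_total: int, col1_total: int, grand_total: int) -> float:
    """P(X = k) for X ~ Hypergeom(grand_total, col1_total, row1_total).

    Probability that a sample of ``row1_total`` drawn without replacement
    from ``grand_total`` items (of which ``col1_total`` are marked) contains
    exactly ``k`` marked items.  Computed in log space.  Infeasible ``k``
    returns 0.
    """
    if row1_total < 0 or col1_total < 0 or grand_total < 0:
        raise ValueError("totals must be non-negative")
    if row1_total > grand_total or col1_total > grand_total:
        raise ValueError("row/col totals cannot exceed the grand total")
    lo = max(0, row1_total + col1_total - grand_total)
    hi = min(row1_total, col1_total)
    if k < lo or k > hi:
        return 0.0
    logp = (
        _log_comb(col1_total, k)
        + _log_comb(grand_total - col1_total, row1_total - k)
        - _log_comb(grand_total, row1_total)
    )
    return float(math.exp(logp))


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact test, sum-of-small-p convention.

    An all-zero table carries no information; by convention p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    # integer numerators over the common denominator C(n, row1)
    nums = [
        math.comb(col1, k) * math.comb(n - col1, row1 - k) for k in range(lo, hi + 1)
    ]
    obs = nums[a - lo]
    denom = math.comb(n, row1)
    p = sum(v for v in nums if v <= obs) / denom
    return min(1.0, max(0.0, p))


def chi_square_enrichment(
    hits_in_set: int, set_size: int, hits_background: int, background_size: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the implied 2x2.

    Rows: the gene set of interest vs. the background set; columns: trait
    present vs. absent.  Returns ``(statistic, p)``.  A zero expected cell is
    a hard error -- use Fisher's exact test instead.
    """
    if not (0 <= hits_in_set <= set_size and 0 <= hits_background <= background_size):
        raise ValueError("hit counts must lie within their set sizes")
    obs = np.array(
        [
            [hits_in_set, set_size - hits_in_set],
            [hits_background, background_size - hits_background],
        ],
        dtype=float,
    )
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if np.any(expected == 0):
        raise ValueError(
            "zero expected cell; the chi-square approximation is undefined -- "
            "use fisher_exact_two_sided"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(_chi2.sf(stat, df=1))


def spearman(x, y) -> float | None:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks.  Returns ``None`` (recorded absent) when
    either vector is constant, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def box_stats(values) -> BoxStats:
    """Box-plot statistics with type-7 (linear-interpolation) quartiles."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    hi_fence = q3 + 1.5 * iqr
    lo_fence = q1 - 1.5 * iqr
    is_out = (v > hi_fence) | (v < lo_fence)
    inliers = v[~is_out]
    return BoxStats(
        q1=q1,
        median=med,
        q3=q3,
        iqr=iqr,
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=sorted(float(x) for x in v[is_out]),
    )
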