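"""Shared statistical primitives.

Every analysis stage funnels its hypothesis tests through this module so
that conventions (two-sided tests, tie handling, degenerate inputs) are
decided once.  The r x c exact contingency test is implemented here by full
enumeration under the multivariate hypergeometric null; the remaining tests
wrap :mod:`scipy.stats` behind a uniform :class:`TestResult` surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "fisher_exact",
    "one_sample_t",
    "mann_whitney",
    "fishers_method",
]

# Tables larger than 2x2 are enumerated exactly; beyond this grand total the
# enumeration is refused rather than silently approximated.
ENUMERATION_LIMIT = 500

# Relative tolerance when comparing point probabilities in the
# probability-ordering rule (same convention as R's fisher.test).
_REL_TOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        t, U or chi-square statistic as applicable (NaN for exact tests
        that have no natural statistic).
    p_value : float
        Two-sided p-value in [0, 1].
    method : str
        Identifier of the procedure actually used, e.g.
        ``"fisher_exact_2x3"`` or ``"mann_whitney_normal_approx"``.
    df : float or None
        Degrees of freedom where applicable.
    n : int or None
        Total sample size used by the test.
    degenerate : bool
        Set when the input was degenerate (e.g. zero variance) and the
        p-value follows a limiting convention rather than a distribution.
    """

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _table_log_prob(table: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    # log P(table | margins) under the multivariate hypergeometric null:
    # prod(Ri!) prod(Cj!) / (N! prod(nij!))
    return float(lr.sum() + lc.sum() - ln - gammaln(table + 1.0).sum())


def _iter_tables(row_totals: np.ndarray, col_totals: np.ndarray):
    """Yield every non-negative integer matrix with the given margins."""
    r = len(row_totals)

    def rec(row_idx: int, remaining_cols: np.ndarray):
        if row_idx == r - 1:
            yield [remaining_cols.copy()]
            return
        total = row_totals[row_idx]
        ranges = [range(min(total, int(c)) + 1) for c in remaining_cols]
        for cells in itertools.product(*ranges):
            if sum(cells) != total:
                continue
            rest = remaining_cols - np.array(cells)
            for tail in rec(row_idx + 1, rest):
                yield [np.array(cells)] + tail

    yield from rec(0, col_totals.copy())


def fisher_exact(table) -> TestResult:
    """Two-sided exact test of independence for an r x c contingency table.

    The p-value is the total null probability of every table with the
    observed margins whose point probability does not exceed that of the
    observed table (probability-ordering rule, the Fisher-Freeman-Halton
    convention).  For 2x2 tables this reduces to the classic two-sided
    Fisher exact test.

    Parameters
    ----------
    table : array-like of int, shape (r, c)
        Non-negative counts, r >= 2 and c >= 2.

    Raises
    ------
    ValueError
        On negative cells, an all-zero table, or a table whose grand total
        exceeds the enumeration limit (no silent approximation is made).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError(f"need an r x c table with r, c >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    n_total = int(t.sum())
    if n_total < 1:
        raise ValueError("contingency table is empty (grand total 0)")
    if t.size > 4 and n_total > ENUMERATION_LIMIT:
        raise ValueError(
            f"enumeration limit: grand total {n_total} exceeds "
            f"{ENUMERATION_LIMIT} for a {t.shape[0]}x{t.shape[1]} table"
        )

    row_totals = t.sum(axis=1)
    col_totals = t.sum(axis=0)
    lr = gammaln(row_totals + 1.0)
    lc = gammaln(col_totals + 1.0)
    ln = float(gammaln(n_total + 1.0))

    obs_lp = _table_log_prob(t, lr, lc, ln)
    cutoff = obs_lp + np.log1p(_REL_TOL)

    if t.shape == (2, 2):
        # the table is determined by its first cell; evaluate the whole
        # support at once
        r1, c1 = int(row_totals[0]), int(col_totals[0])
        lo = max(0, c1 - int(row_totals[1]))
        hi = min(r1, c1)
        a = np.arange(lo, hi + 1)
        cells = np.stack([a, r1 - a, c1 - a, n_total - r1 - c1 + a], axis=1)
        lp = lr.sum() + lc.sum() - ln - gammaln(cells + 1.0).sum(axis=1)
        p = float(np.exp(lp[lp <= cutoff]).sum())
    else:
        p = 0.0
        for rows in _iter_tables(row_totals, col_totals):
            lp = _table_log_prob(np.vstack(rows), lr, lc, ln)
            if lp <= cutoff:
                p += float(np.exp(lp))
    p = min(p, 1.0)
    return TestResult(
        statistic=float("nan"),
        p_value=p,
        method=f"fisher_exact_{t.shape[0]}x{t.shape[1]}",
        n=n_total,
    )


def one_sample_t(values, null_mean: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of mean(values) == null_mean.

    On log2-ratio data with ``null_mean=0`` this tests the null of a
    field/reference expression ratio of 1.

    Zero-variance inputs are handled by convention: p = 1 when the common
    value equals the null, p = 0 otherwise, with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in t-test input")
    n = x.size
    if np.ptp(x) == 0.0:
        same = bool(x[0] == null_mean)
        return TestResult(
            statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            method="one_sample_t",
            df=n - 1,
            n=n,
            degenerate=True,
        )
    res = sps.ttest_1samp(x, popmean=null_mean)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="one_sample_t",
        df=n - 1,
        n=n,
    )


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test (rank-sum) for two independent groups.

    The exact null distribution is used when n1 + n2 <= 20 and the pooled
    data contain no ties; otherwise the normal approximation with tie and
    continuity correction is used.  The choice is recorded in ``method``.
    The reported statistic is U of the first group; U1 + U2 = n1*n2 always.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney needs at least one value per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= 20) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann_whitney_exact" if exact else "mann_whitney_normal_approx",
        n=int(x.size + y.size),
    )


def fishers_method(p_values) -> TestResult:
    """Combine independent p-values by Fisher's method.

    X^2 = -2 * sum(ln p_i) is referred to the chi-square distribution with
    2k degrees of freedom; the combined p is the upper tail.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("fishers_method needs at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return TestResult(
        statistic=stat,
        p_value=float(sps.chi2.sf(stat, df)),
        method="fishers_method",
        df=df,
        n=p.size,
    )
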