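"""Statistical primitives used throughout the pipeline.

Every test here is implemented from its definitional formula (rank
statistics, tie corrections, exact small-sample enumeration), relying on
scipy only for reference distribution tails (normal, t, chi-squared,
hypergeometric).  Conventions:

* all p-values are two-sided;
* ``direction`` is the sign of the *later* group minus the *earlier*
  group (so an MI-enriched feature is +1 in an HC-vs-MI comparison);
* Mann-Whitney / Wilcoxon rank-sum switches to exact enumeration of the
  permutation distribution when the pooled sample size is at most 12,
  and otherwise uses the tie-corrected normal approximation with
  continuity correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from scipy.stats import rankdata

EXACT_MAX_N = 12  # pooled size at or below which rank tests enumerate exactly


class DegenerateMarginError(ValueError):
    """A contingency-table row or column sums to zero."""


class OrderTestError(ValueError):
    """Trend test invoked with fewer than 3 non-empty groups."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    direction: int  # +1 second/later group larger, -1 smaller, 0 tie
    method: str

    def __post_init__(self) -> None:
        self.p_value = float(min(1.0, max(0.0, self.p_value)))
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")


def _tie_sizes(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


# ---------------------------------------------------------------------------
# Two-group rank-sum (Mann-Whitney / Wilcoxon)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U counting pairs where y exceeds x, ties as 1/2."""
    diff = y[:, None] - x[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all C(n+m, n) group assignments when
    n + m <= ``EXACT_MAX_N``; otherwise normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1 or n + m < 2:
        raise ValueError("each group needs >= 1 observation")
    u = _u_statistic(x, y)
    mu = n * m / 2.0
    direction = int(np.sign(u - mu))

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(u, 1.0, 0, "wilcoxon")

    if n + m <= EXACT_MAX_N:
        dev = abs(u - mu)
        total = 0
        hits = 0
        idx = np.arange(n + m)
        for comb in itertools.combinations(idx, m):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u_p = _u_statistic(pooled[~mask], pooled[mask])
            total += 1
            if abs(u_p - mu) >= dev - 1e-12:
                hits += 1
        return TestResult(u, hits / total, direction, "wilcoxon")

    big_n = n + m
    ties = _tie_sizes(pooled)
    tie_term = ((ties**3 - ties).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, 0, "wilcoxon")
    cc = 0.5 * np.sign(u - mu)
    z = (u - mu - cc) / np.sqrt(var)
    p = 2.0 * _sps.norm.sf(abs(z))
    return TestResult(u, min(1.0, p), direction, "wilcoxon")


def t_test_welch(x, y) -> TestResult:
    """Two-sided Welch t-test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    direction = int(np.sign(my - mx))
    se2 = vx / len(x) + vy / len(y)
    if se2 == 0:
        return TestResult(0.0, 1.0 if mx == my else 0.0, direction, "ttest")
    t = (my - mx) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(t, p, direction, "ttest")


# ---------------------------------------------------------------------------
# k-group tests


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-squared reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    big_n = len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, 0, "kruskal")
    ranks = rankdata(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        h += len(g) * (r.mean() - (big_n + 1) / 2.0) ** 2
        offset += len(g)
    h *= 12.0 / (big_n * (big_n + 1))
    ties = _tie_sizes(pooled)
    correction = 1.0 - (ties**3 - ties).sum() / (big_n**3 - big_n)
    if correction <= 0:
        return TestResult(0.0, 1.0, 0, "kruskal")
    h /= correction
    p = _sps.chi2.sf(h, len(groups) - 1)
    return TestResult(h, p, 0, "kruskal")


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            jt += _u_statistic(groups[i], groups[j])
    return jt


def _jt_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """Mean and tie-adjusted variance of the JT null distribution."""
    ns = np.array([len(g) for g in groups], dtype=float)
    big_n = ns.sum()
    pooled = np.concatenate(groups)
    t = _tie_sizes(pooled).astype(float)
    mu = (big_n**2 - (ns**2).sum()) / 4.0
    term1 = (
        big_n * (big_n - 1) * (2 * big_n + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum()
        * (t * (t - 1) * (t - 2)).sum()
        / (36.0 * big_n * (big_n - 1) * (big_n - 2))
    )
    term3 = (
        (ns * (ns - 1)).sum() * (t * (t - 1)).sum() / (8.0 * big_n * (big_n - 1))
    )
    return mu, term1 + term2 + term3


def _enumerate_assignments(pooled: np.ndarray, sizes: list[int]):
    """Yield all distinct index partitions of ``pooled`` into ordered groups."""
    idx = tuple(range(len(pooled)))

    def rec(remaining: tuple, k: int):
        if k == len(sizes) - 1:
            yield (remaining,)
            return
        for comb in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(comb))
            for tail in rec(rest, k + 1):
                yield (comb,) + tail

    yield from rec(idx, 0)


def jonckheere_terpstra(groups, exact_max_n: int = EXACT_MAX_N) -> TestResult:
    """Jonckheere-Terpstra trend test for ordered groups.

    Statistic is the sum of pairwise Mann-Whitney counts over all
    ordered group pairs.  Exact enumeration of the permutation
    distribution when the pooled size is at most ``exact_max_n``;
    otherwise a normal approximation with tie-adjusted variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups]
    if sum(len(g) > 0 for g in groups) < 3:
        raise OrderTestError("trend test needs >= 3 non-empty ordered groups")
    jt = _jt_statistic(groups)
    mu, var = _jt_moments(groups)
    direction = int(np.sign(jt - mu))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return TestResult(jt, 1.0, 0, "jt")

    if len(pooled) <= exact_max_n:
        sizes = [len(g) for g in groups]
        dev = abs(jt - mu)
        total = 0
        hits = 0
        for parts in _enumerate_assignments(pooled, sizes):
            gs = [pooled[list(p)] for p in parts]
            jt_p = _jt_statistic(gs)
            total += 1
            if abs(jt_p - mu) >= dev - 1e-12:
                hits += 1
        return TestResult(jt, hits / total, direction, "jt")

    if var <= 0:
        return TestResult(jt, 1.0, 0, "jt")
    # continuity correction: JT moves in steps of 1 for untied data
    z = max(abs(jt - mu) - 0.5, 0.0) / np.sqrt(var)
    p = 2.0 * _sps.norm.sf(z)
    return TestResult(jt, min(1.0, p), direction, "jt")


# ---------------------------------------------------------------------------
# Contingency tests


def chi_square_contingency(counts) -> TestResult:
    """Pearson chi-squared for an r x c table, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    total = counts.sum()
    if total < 1:
        raise ValueError("grand total must be >= 1")
    if (row == 0).any() or (col == 0).any():
        raise DegenerateMarginError("a margin of the table sums to zero")
    expected = np.outer(row, col) / total
    stat = ((counts - expected) ** 2 / expected).sum()
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = _sps.chi2.sf(stat, df)
    return TestResult(stat, p, 0, "chi2")


def fisher_exact_2x2(counts) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric summation."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    a, b = counts[0]
    c, d = counts[1]
    row1, row2 = a + b, c + d
    col1 = a + c
    total = counts.sum()
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        raise DegenerateMarginError("a margin of the table sums to zero")
    # hypergeometric over the value in cell (0, 0)
    lo = int(max(0, col1 - row2))
    hi = int(min(col1, row1))
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, int(total), int(row1), int(col1))
    p_obs = _sps.hypergeom.pmf(int(a), int(total), int(row1), int(col1))
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    if p > 1.0 - 1e-12:
        p = 1.0
    expected_a = row1 * col1 / total
    direction = int(np.sign(expected_a - a))  # +1: second row enriched in col1
    return TestResult(float(a), p, direction, "fisher")


# ---------------------------------------------------------------------------
# Effect size and multiplicity


def fold_change(x, y, pseudocount: float = 0.0, center: str = "mean") -> float:
    """Case-over-reference ratio of group centers with a shared pseudocount.

    ``y`` is the case group, ``x`` the reference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fn = np.mean if center == "mean" else np.median
    cx, cy = float(fn(x)), float(fn(y))
    if cx + pseudocount == 0:
        if cy + pseudocount == 0:
            raise ZeroDivisionError("both group centers are zero with zero pseudocount")
        raise ZeroDivisionError("reference center zero with zero pseudocount")
    return (cy + pseudocount) / (cx + pseudocount)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
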