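"""Uncertainty-aware choropleth classification.

A class break between two consecutive sorted observations is scored by the
separability of their confidence intervals: breaks placed where intervals
barely overlap are defensible under measurement uncertainty, breaks through
heavily overlapping intervals are not. Break placement is optimized exactly
by dynamic programming on the sorted order, either for mean separability
alone or for a 50/50 combination with the goodness-of-variance fit (the
Jenks criterion). Quantile (tertile) classification is the uncertainty-blind
baseline.

Separability of the straddling pair, this package's concrete definition:
with sorted intervals [l1,h1], [l2,h2], signed gap d = l2 - h1, pair union
U = max(h) - min(l) and mean half-width hw = ((h1-l1) + (h2-l2))/2,

    score = 1                      if d >= hw and d > 0 (clearly disjoint)
          = clip((d + hw)/U, 0, 1) otherwise.

Identical intervals score 0; fully disjoint, well-separated intervals score
1; partial overlap scores in between. The score is invariant under joint
affine rescaling of values and errors.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy import stats

__all__ = [
    "ClassedMap",
    "tract_intervals",
    "break_separability",
    "optimize_breaks",
    "quantile_breaks",
]

log = logging.getLogger(__name__)


@dataclass
class ClassedMap:
    k: int
    breaks: np.ndarray  # (k-1,) ordered cut values
    assignment: np.ndarray  # class index per observation, 0..k-1
    separability: np.ndarray | None  # per-break score in [0, 1]
    objective: float | None
    criterion: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        counts = np.bincount(self.assignment, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("empty class")


def tract_intervals(values, errors, level: float = 0.95) -> np.ndarray:
    """Per-tract symmetric Normal confidence intervals, shape (n, 2).

    Interval = value +/- z_{(1+level)/2} * error.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if np.any(errors < 0):
        raise ValueError("errors must be non-negative")
    z = stats.norm.ppf(0.5 * (1 + level))
    return np.column_stack([values - z * errors, values + z * errors])


def _pair_separability(lo1, hi1, lo2, hi2) -> float:
    d = lo2 - hi1
    union = max(hi1, hi2) - min(lo1, lo2)
    hw = 0.5 * ((hi1 - lo1) + (hi2 - lo2))
    if d > 0 and d >= hw:
        return 1.0
    if union <= 0:
        return 0.0
    return float(np.clip((d + hw) / union, 0.0, 1.0))


def break_separability(intervals: np.ndarray, position: int) -> float:
    """Separability of the break before sorted observation ``position``.

    ``intervals`` are the (n, 2) confidence intervals in sorted-value
    order; ``position`` in 1..n-1 places the break between observations
    position-1 and position.
    """
    n = intervals.shape[0]
    if not 1 <= position <= n - 1:
        raise ValueError("break position must be between two observations")
    lo1, hi1 = intervals[position - 1]
    lo2, hi2 = intervals[position]
    return _pair_separability(lo1, hi1, lo2, hi2)


def _class_sse(values: np.ndarray) -> np.ndarray:
    """sse[i, j] = within-class sum of squares of sorted values[i:j+1]."""
    n = values.size
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    s = c1[j + 1] - c1[i]
    ss = c2[j + 1] - c2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        sse = ss - s**2 / cnt
    sse[cnt < 1] = np.inf
    return np.maximum(sse, 0.0)


def optimize_breaks(
    values,
    intervals,
    k: int,
    criterion: str = "separability",
    w: float = 0.5,
) -> ClassedMap:
    """Exact optimal break placement by dynamic programming.

    ``criterion="separability"`` maximizes the mean per-break separability
    score; ``"combined"`` maximizes w * GVF + (1 - w) * mean separability,
    where GVF = 1 - SDCM/SDAM is the goodness-of-variance fit. Ties are
    broken toward equal class sizes. Breaks are reported as midpoints
    between the straddling sorted values.
    """
    values = np.asarray(values, dtype=float)
    intervals = np.asarray(intervals, dtype=float)
    n = values.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more classes than observations")
    if np.ptp(values) == 0:
        raise ValueError("all values equal")
    if criterion not in ("separability", "combined"):
        raise ValueError(f"unknown criterion {criterion!r}")

    order = np.argsort(values, kind="stable")
    v = values[order]
    iv = intervals[order]
    sep = np.array(
        [_pair_separability(*iv[i - 1], *iv[i]) for i in range(1, n)]
    )  # sep[i-1] scores a break before sorted obs i

    sdam = float(((v - v.mean()) ** 2).sum())
    if criterion == "combined":
        sse = _class_sse(v)
        w_sep = (1.0 - w) / (k - 1)
    else:
        sse = None
        w_sep = 1.0 / (k - 1)

    target = n / k  # for the equal-size tie-break
    NEG = -np.inf
    # dp[c][i]: best additive objective for sorted obs 0..i-1 in c classes.
    dp = np.full((k + 1, n + 1), NEG)
    tie = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    tie[0][0] = 0.0
    for c in range(1, k + 1):
        for i in range(c, n - (k - c) + 1):
            best, best_tie, best_j = NEG, np.inf, -1
            for j in range(c - 1, i):
                if dp[c - 1][j] == NEG:
                    continue
                gain = 0.0
                if c > 1:
                    gain += w_sep * sep[j - 1]
                if sse is not None:
                    gain += -w * sse[j, i - 1] / sdam
                cand = dp[c - 1][j] + gain
                cand_tie = tie[c - 1][j] + (i - j - target) ** 2
                if cand > best + 1e-12 or (
                    cand > best - 1e-12 and cand_tie < best_tie
                ):
                    best, best_tie, best_j = cand, cand_tie, j
            dp[c][i] = best
            tie[c][i] = best_tie
            back[c][i] = best_j

    if dp[k][n] == NEG:
        raise RuntimeError("no feasible classification")
    cuts = []
    i = n
    for c in range(k, 0, -1):
        j = back[c][i]
        if c > 1:
            cuts.append(j)
        i = j
    cuts = sorted(cuts)  # break before sorted obs index j

    breaks = np.array([(v[j - 1] + v[j]) / 2.0 for j in cuts])
    sep_scores = np.array([sep[j - 1] for j in cuts])
    assignment_sorted = np.zeros(n, dtype=int)
    for j in cuts:
        assignment_sorted[j:] += 1
    assignment = np.empty(n, dtype=int)
    assignment[order] = assignment_sorted

    objective = float(w_sep * sep_scores.sum())
    if sse is not None:
        bounds = [0] + cuts + [n]
        sdcm = sum(sse[a, b - 1] for a, b in zip(bounds[:-1], bounds[1:]))
        objective += float(w * (1.0 - sdcm / sdam))
    return ClassedMap(
        k=k,
        breaks=breaks,
        assignment=assignment,
        separability=sep_scores,
        objective=objective,
        criterion=criterion,
    )


def quantile_breaks(values, k: int, intervals=None) -> ClassedMap:
    """Quantile classification: breaks at the j/k empirical quantiles.

    k = 3 gives the tertile baseline. If massive ties would empty a class,
    quantiles of the distinct values are used instead (logged).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more classes than observations")
    qs = np.arange(1, k) / k
    breaks = np.quantile(values, qs)
    if np.any(np.diff(breaks) <= 0) or _has_empty(values, breaks, k):
        distinct = np.unique(values)
        if distinct.size < k:
            raise ValueError("too few distinct values for k classes")
        breaks = np.quantile(distinct, qs)
        log.warning("ties made quantile classes empty; used distinct-value quantiles")
    assignment = np.searchsorted(breaks, values, side="right")
    sep_scores = None
    if intervals is not None:
        intervals = np.asarray(intervals, dtype=float)
        order = np.argsort(values, kind="stable")
        iv = intervals[order]
        v = values[order]
        sep_scores = np.array(
            [
                break_separability(iv, int(np.searchsorted(v, b, side="right")))
                for b in breaks
            ]
        )
    return ClassedMap(
        k=k,
        breaks=breaks,
        assignment=assignment,
        separability=sep_scores,
        objective=None,
        criterion="quantile",
    )


def _has_empty(values: np.ndarray, breaks: np.ndarray, k: int) -> bool:
    assignment = np.searchsorted(breaks, values, side="right")
    return bool(np.any(np.bincount(assignment, minlength=k) == 0))
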