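"""Statistical comparisons applied to the derived session statistics.

Only the bespoke-adjacent pieces live here: the Sidak multiple-comparison
correction, the paired Wilcoxon signed-rank test (exact by enumeration at
small n), and Welch's unequal-variance t-test. Omnibus repeated-measures
ANOVAs are routine and deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "sidak_adjust",
    "paired_signed_rank",
    "welch_t",
]

EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_raw: float
    method: str
    n: tuple[int, ...]
    df: float | None = None
    p_adjusted: float | None = None
    note: str = ""

    def adjusted(self, m: int) -> "ComparisonResult":
        """Copy with a Sidak-adjusted p for a family of ``m`` comparisons."""
        p_adj = float(sidak_adjust([self.p_raw], m)[0]) if np.isfinite(self.p_raw) else np.nan
        return ComparisonResult(
            self.statistic, self.p_raw, self.method, self.n, self.df, p_adj, self.note
        )


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Sidak correction: p_adj = 1 - (1 - p)^m, capped at 1.

    ``m`` defaults to the number of p-values. Order-preserving and monotone
    in both p and m.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Ranks of |d| use midranks for ties. Under the symmetric null each rank
    enters the positive-rank sum W+ independently with probability 1/2; the
    two-sided p is P(|W - mu| >= |w - mu|) over all 2^n sign patterns.
    Returns (W+, p).
    """
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    obs_dev = abs(w_obs - mu)
    n = d.size
    count = 0
    for signs in product((0.0, 1.0), repeat=n):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    return w_obs, count / 2.0**n


def paired_signed_rank(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-tailed paired Wilcoxon signed-rank test on a - b.

    Zero differences are dropped before ranking (Wilcoxon's convention);
    tied magnitudes share midranks. The p-value is exact (full enumeration
    of sign patterns) for up to 12 nonzero differences, and the normal
    approximation beyond. The reported statistic is W+, the positive-rank
    sum. All-zero differences give an undefined (NaN) result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    n_pairs = int(a.size)
    if d.size == 0:
        return ComparisonResult(
            np.nan, np.nan, "wilcoxon-signed-rank", (n_pairs,),
            note="undefined: all paired differences are zero",
        )
    if d.size <= EXACT_ENUMERATION_MAX_N:
        w, p = _exact_signed_rank_p(d)
        method = "wilcoxon-signed-rank-exact"
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        ranks = sps.rankdata(np.abs(d))
        w = float(ranks[d > 0].sum())
        p = float(res.pvalue)
        method = "wilcoxon-signed-rank-normal"
    return ComparisonResult(w, float(p), method, (n_pairs,))


def welch_t(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Two-tailed Welch's t-test with Satterthwaite degrees of freedom.

    Requires at least two observations per group; two zero-variance groups
    give an undefined result (NaN) unless their means differ, which is an
    infinite-t degenerate case also reported as undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return ComparisonResult(
            np.nan, np.nan, "welch-t", (int(x.size), int(y.size)),
            note="undefined: both groups have zero variance",
        )
    t, p = sps.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
    return ComparisonResult(float(t), float(p), "welch-t", (int(x.size), int(y.size)), df=float(df))
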