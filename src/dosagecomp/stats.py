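"""Nonparametric two-sample tests on class-level expression ratios.

Two tests are provided, both two-sided and both depending on the data
only through ranks (hence invariant under monotone transforms such as
log2):

* Mood's median test: a 2x2 table of counts above vs at-or-below the
  pooled grand median, tested by the 1-df chi-square without continuity
  correction, switching automatically to the exact conditional
  (hypergeometric / Fisher) test when any expected cell is below 5.
* A permutation test on the absolute difference of group medians, with
  group labels permuted over the pooled values; exhaustive enumeration
  replaces Monte-Carlo sampling automatically whenever the total number
  of distinct splits does not exceed ``n_perm``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "MedianTestResult",
    "PermutationTestResult",
    "moods_median_test",
    "permutation_median_diff_test",
    "format_p",
]


@dataclass(frozen=True)
class MedianTestResult:
    statistic: float          # chi-square (nan when the exact test is used)
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: above, at-or-below
    method: str               # "chisq" | "fisher" | "degenerate"
    grand_median: float


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float           # |median(a) - median(b)|
    p_value: float
    n_perm: int               # permutations evaluated
    seed: int | None
    exact: bool               # True when all splits were enumerated


def _chi2_2x2(table: np.ndarray) -> float:
    """Closed-form 1-df chi-square for a 2x2 table, no continuity correction."""
    (a, b), (c, d) = table
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


def moods_median_test(x, y, *, ties: str = "below",
                      method: str = "auto") -> MedianTestResult:
    """Mood's median test for a difference in location between two samples.

    Values tied with the pooled grand median are counted in the
    at-or-below row by default (``ties="below"``); ``ties="ignore"``
    drops them instead. ``method`` is ``"auto"`` (chi-square, switching
    to the exact conditional test when any expected cell count is below
    5), ``"chisq"`` or ``"fisher"``. A pooled sample with no variation
    is degenerate and returns p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if ties not in ("below", "ignore"):
        raise ValueError(f"unknown ties policy {ties!r}")
    if method not in ("auto", "chisq", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    m = float(np.median(pooled))
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; median test is degenerate")
        table = ((0, 0), (len(x), len(y)))
        return MedianTestResult(math.nan, 1.0, table, "degenerate", m)

    def split(v):
        above = int((v > m).sum())
        if ties == "below":
            below = int((v <= m).sum())
        else:
            below = int((v < m).sum())
        return above, below

    ax, bx = split(x)
    ay, by = split(y)
    table = np.array([[ax, ay], [bx, by]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    use_fisher = method == "fisher" or (method == "auto" and (expected < 5).any())
    if use_fisher:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return MedianTestResult(math.nan, float(p),
                                ((ax, ay), (bx, by)), "fisher", m)
    chi2 = _chi2_2x2(table)
    if math.isnan(chi2):
        warnings.warn("degenerate margin in median test table")
        return MedianTestResult(math.nan, 1.0, ((ax, ay), (bx, by)),
                                "degenerate", m)
    p = float(sps.chi2.sf(chi2, df=1))
    return MedianTestResult(float(chi2), p, ((ax, ay), (bx, by)), "chisq", m)


def permutation_median_diff_test(a, b, n_perm: int = 10_000,
                                 seed: int | None = None) -> PermutationTestResult:
    """Permutation test on the absolute difference of sample medians.

    Labels are permuted over the pooled values. When the number of
    distinct splits C(n, |a|) is at most ``n_perm`` every split is
    enumerated and the p-value is exact (#{splits with statistic >=
    observed} / #splits); otherwise ``n_perm`` random relabellings give
    the valid Monte-Carlo estimate (k + 1) / (n_perm + 1). Fixed ``seed``
    gives a bit-for-bit reproducible p-value.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    observed = abs(float(np.median(a)) - float(np.median(b)))

    total = math.comb(n, na)
    if total <= n_perm:
        count = 0
        idx = np.arange(n)
        for left in combinations(idx, na):
            left = np.array(left)
            mask = np.zeros(n, bool)
            mask[left] = True
            stat = abs(float(np.median(pooled[mask]))
                       - float(np.median(pooled[~mask])))
            if stat >= observed - 1e-12:
                count += 1
        return PermutationTestResult(observed, count / total, total, seed, True)

    rng = np.random.default_rng(seed)
    # permute rows of a tiled pooled matrix, then split columns;
    # chunked so pooled samples of ~1e4 genes stay within memory
    k = 0
    chunk = max(1, int(2e7) // n)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mat = np.broadcast_to(pooled, (m, n)).copy()
        mat = rng.permuted(mat, axis=1)
        stats_ = np.abs(np.median(mat[:, :na], axis=1)
                        - np.median(mat[:, na:], axis=1))
        k += int((stats_ >= observed - 1e-12).sum())
        done += m
    p = (k + 1) / (n_perm + 1)
    return PermutationTestResult(observed, p, n_perm, seed, False)


def format_p(p: float, floor: float = 1e-4) -> str:
    """Human-readable p-value with a reporting floor (default '< 1e-04')."""
    if p < floor:
        return f"< {floor:.0e}"
    return f"{p:.4g}"
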