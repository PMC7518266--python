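"""Statistical toolkit: exact small-n Spearman machinery plus standard tests.

The exact Spearman branch enumerates all n! rank permutations (n <= 9)
of the permutation null and reports a two-sided p-value as the doubled
tail of the statistic S = sum of squared rank differences, capped at 1.
This reproduces printed values for tiny experimental sample sizes where
asymptotic approximations are meaningless.

Reported p-values below 1e-30 are formatted as "<1e-30" (the raw value
is retained on the result object).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "P_FLOOR",
    "spearman_from_s",
    "spearman_s_distribution",
    "spearman_exact",
    "wilcoxon_signed",
    "mann_whitney",
    "pearson",
]

P_FLOOR = 1e-30
EXACT_MAX_N = 9


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``n`` is the effective sample size the p-value was computed on;
    ``extras`` carries statistic-specific values (e.g. the Spearman S).
    """

    __test__ = False  # keep pytest from collecting this as a test class

    name: str
    statistic: float
    n: int
    p_two_sided: float
    extras: dict = field(default_factory=dict)

    @property
    def p_floor_applied(self) -> bool:
        return self.p_two_sided < P_FLOOR

    def formatted_p(self) -> str:
        if self.p_floor_applied:
            return "<1e-30"
        return f"{self.p_two_sided:.3g}"


def spearman_from_s(S: float, n: int) -> float:
    """Spearman rho from the statistic S = sum of squared rank differences.

    Uses the no-ties identity rho = 1 - 6 S / (n (n^2 - 1)).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if S < 0:
        raise ValueError("S must be non-negative")
    return 1.0 - 6.0 * S / (n * (n * n - 1))


@lru_cache(maxsize=16)
def spearman_s_distribution(n: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Exact permutation-null distribution of S for sample size n.

    Enumerates all n! permutations of ranks 1..n against the identity
    ranking and tallies S.  Returns (sorted distinct S values, counts).
    """
    counts: Counter[int] = Counter()
    base = range(n)
    for perm in itertools.permutations(base):
        counts[sum((i - r) ** 2 for i, r in enumerate(perm))] += 1
    svals = tuple(sorted(counts))
    return svals, tuple(counts[s] for s in svals)


def _exact_two_sided_p(S: int, n: int) -> float:
    svals, counts = spearman_s_distribution(n)
    total = math.factorial(n)
    lower = sum(c for s, c in zip(svals, counts) if s <= S)
    upper = sum(c for s, c in zip(svals, counts) if s >= S)
    return min(1.0, 2.0 * min(lower, upper) / total)


def _rank(x: Sequence[float]) -> np.ndarray:
    return sps.rankdata(np.asarray(x, dtype=float))


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman correlation with an exact enumeration p-value for n <= 9.

    The exact branch requires tie-free data; with ties, or for larger
    samples, the standard large-sample test is used instead (with a
    warning in the tie case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations")
    rx, ry = _rank(x), _rank(y)
    tied = len(set(rx)) < n or len(set(ry)) < n
    if tied or n > EXACT_MAX_N:
        if tied and n <= EXACT_MAX_N:
            warnings.warn("ties present: falling back to the large-sample Spearman test")
        rho, p = sps.spearmanr(x, y)
        return TestResult("spearman", float(rho), n, float(p), {"exact": False})
    S = int(round(np.sum((rx - ry) ** 2)))
    rho = spearman_from_s(S, n)
    p = _exact_two_sided_p(S, n)
    return TestResult("spearman_exact", rho, n, p, {"S": S, "exact": True})


def wilcoxon_signed(
    values: Sequence[float], mu: float = 0.0, n_genes: int | None = None
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of location against ``mu``.

    ``values`` may be the flattened genes x replicates dLFE values (the
    pipeline's convention of treating each randomization repetition as
    an observation); ``n_genes`` records the underlying number of genes
    so the pseudo-replication is visible in the result.
    """
    v = np.asarray(values, dtype=float) - mu
    v = v[v != 0.0]
    if v.size == 0:
        raise ValueError("all deviations are zero")
    stat, p = sps.wilcoxon(v, alternative="two-sided")
    extras = {}
    if n_genes is not None:
        extras["n_genes"] = n_genes
    return TestResult("wilcoxon_signed", float(stat), int(v.size), float(p), extras)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult("mann_whitney", float(stat), int(a.size + b.size), float(p))


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Pearson product-moment correlation test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), len(x), float(p))
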