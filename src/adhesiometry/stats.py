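"""Group statistics and significance reporting.

The statistical layer used across the assays: Welch's unpaired t-test,
the Wilcoxon rank-sum test (exact by enumeration for small samples,
normal approximation with tie and continuity corrections otherwise),
Spearman's rank correlation (exact permutation p for small n), the
significance-star convention, and the cross-assay correlation report
relating single-cell adhesion forces to population aggregate areas.

All tests are two-sided.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "VariantPoint",
    "t_test_unpaired",
    "wilcoxon_rank_sum",
    "spearman",
    "significance_stars",
    "correlate_variants",
    "WILCOXON_EXACT_MAX_N",
    "SPEARMAN_EXACT_MAX_N",
]

#: exact enumeration is used when n1 + n2 does not exceed this
WILCOXON_EXACT_MAX_N = 12
#: exact permutation p-value for Spearman up to this many pairs
SPEARMAN_EXACT_MAX_N = 7


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    stars: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")


@dataclass(frozen=True)
class VariantPoint:
    """One adhesin variant's paired single-cell and population readout."""

    variant: str
    mean_fmax_nN: float
    total_aggregate_area: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.mean_fmax_nN, self.total_aggregate_area]).all():
            raise ValueError("variant point values must be finite")


def significance_stars(p: float) -> str:
    """Map a p-value to the star convention.

    p > 0.05 is not significant (``n.s``); 0.05 >= p > 0.01 earns ``*``;
    0.01 >= p > 0.001 earns ``**``; p <= 0.001 earns ``***``.  The
    boundaries are inclusive on the more-significant side, so p = 0.05 is
    ``*`` and p = 0.001 is ``***``.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p > 0.05:
        return "n.s"
    if p > 0.01:
        return "*"
    if p > 0.001:
        return "**"
    return "***"


def t_test_unpaired(a, b) -> TestResult:
    """Welch's two-sided unpaired t-test.

    The unequal-variance form is used throughout since group spreads in
    adhesion data routinely differ.  Two degenerate equal samples (zero
    variance, equal means) report statistic 0, p 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return TestResult("t_unpaired", 0.0, 1.0, len(a), len(b), "n.s")
        raise ValueError("both samples are constant with different means: t undefined")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("t_unpaired", float(stat), float(p), len(a), len(b), significance_stars(float(p)))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is the rank sum of the first sample over the pooled
    midranks.  For n1 + n2 <= 12 the p-value is exact: every assignment
    of the pooled midranks to the first group is enumerated and the
    smaller tail probability is doubled (capped at 1).  Larger samples
    use the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 < 3 or n2 < 3:
        raise ValueError("each sample needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult("wilcoxon_rank_sum", float(n1 * (n1 + n2 + 1) / 2.0), 1.0,
                          n1, n2, "n.s")
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= WILCOXON_EXACT_MAX_N:
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=np.float64
        )
        eps = 1e-9
        p_lo = np.count_nonzero(sums <= w + eps) / len(sums)
        p_hi = np.count_nonzero(sums >= w - eps) / len(sums)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mean_w = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            p = 1.0
        else:
            # continuity correction toward the mean
            z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
            p = float(2.0 * sps.norm.sf(abs(z)))
            p = min(1.0, p)
    return TestResult("wilcoxon_rank_sum", w, p, n1, n2, significance_stars(p))


def spearman(x, y) -> TestResult:
    """Spearman's rank correlation with two-sided p.

    rho is the Pearson correlation of midranks.  For n <= 7 the p-value
    is exact: all n! permutations of one variable's ranks are enumerated
    and p = P(|rho_perm| >= |rho_obs|).  Larger n uses the
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (same length)")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = _midranks(x)
    ry = _midranks(y)
    if np.var(rx) == 0 or np.var(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        sx = rx - rx.mean()
        denom = np.sqrt(np.sum(sx**2))
        count = 0
        total = 0
        eps = 1e-12
        for perm in permutations(ry):
            py = np.asarray(perm) - ry.mean()
            r = float(np.dot(sx, py) / (denom * np.sqrt(np.sum(py**2))))
            total += 1
            if abs(r) >= abs(rho) - eps:
                count += 1
        p = count / total
    else:
        # t approximation on n-2 degrees of freedom
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult("spearman", rho, p, n, n, significance_stars(p))


def correlate_variants(points: list[VariantPoint]) -> tuple[TestResult, pd.DataFrame]:
    """Rank-correlate single-cell F_max with population aggregate area.

    One point per adhesin variant: its mean maximum adhesion force and
    its total aggregate area.  Returns the Spearman test result and the
    point table (with ranks) for plotting or export.
    """
    if len(points) < 3:
        raise ValueError(f"need at least 3 variants, got {len(points)}")
    fmax = [p.mean_fmax_nN for p in points]
    area = [p.total_aggregate_area for p in points]
    result = spearman(fmax, area)
    table = pd.DataFrame(
        {
            "variant": [p.variant for p in points],
            "mean_fmax_nN": fmax,
            "total_aggregate_area": area,
            "rank_fmax": _midranks(np.asarray(fmax)),
            "rank_area": _midranks(np.asarray(area)),
        }
    )
    return result, table
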