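"""The three statistical primitives behind every inference in the pipeline.

* a pooled two-proportion z-test (the "two-proportion T-test" of the amplicon
  SIP literature) for per-phylotype enrichment between paired libraries,
* Benjamini-Hochberg step-up FDR adjustment across a test family,
* the Wilcoxon rank-sum (Mann-Whitney) test for rate and peak-ratio
  comparisons, exact for small untied samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "two_proportion_test",
    "two_proportion_z",
    "bh_adjust",
    "wilcoxon_rank_sum",
]

Alternative = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: Alternative
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> str:
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    return alternative


def two_proportion_z(
    x1, n1, x2, n2, *, continuity: bool = False
) -> np.ndarray:
    """Vectorized pooled two-proportion z statistic.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Degenerate cases (pooled proportion 0 or 1, zero standard error) give
    z = 0 so the corresponding p-value is 1 under any sidedness convention
    used downstream.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("group sizes must be positive")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > n1) or np.any(x2 > n2):
        raise ValueError("successes must satisfy 0 <= x <= n")
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    diff = p1 - p2
    if continuity:
        cc = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = np.sign(diff) * np.maximum(np.abs(diff) - cc, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, diff / np.sqrt(var), 0.0)
    return z


def two_proportion_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: Alternative = "two_sided",
    *,
    continuity: bool = False,
) -> TestResult:
    """Pooled two-proportion z-test of H0: p1 = p2.

    ``alternative='greater'`` tests p1 > p2 (the directional enrichment claim
    used for responder detection).  Identical proportions give p = 1; a zero
    pooled standard error (all successes or all failures) also gives p = 1.
    """
    _check_alternative(alternative)
    z = float(two_proportion_z(x1, n1, x2, n2, continuity=continuity))
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0) or p1 == p2:
        p = 1.0
    elif alternative == "two_sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    else:
        p = float(sps.norm.cdf(z))
    return TestResult(
        statistic=z,
        p_value=min(p, 1.0),
        alternative=alternative,
        method="two-proportion z-test (pooled)",
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("all p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def _rank_sum_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank sum of sample ``a`` using midranks for ties."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    return float(ranks[: a.size].sum())


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: Alternative = "two_sided",
    *,
    exact_max_n: int = 12,
) -> TestResult:
    """Wilcoxon rank-sum test of whether ``a`` tends to exceed ``b``.

    The reported statistic is the rank sum W of sample ``a`` (midranks for
    ties).  The p-value is exact (full enumeration of the rank distribution)
    when the pooled sample size is at most ``exact_max_n`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction is used.
    """
    _check_alternative(alternative)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (a.size + b.size) <= exact_max_n and not ties
    scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = sps.mannwhitneyu(
        a, b, alternative=scipy_alt, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=_rank_sum_statistic(a, b),
        p_value=min(float(res.pvalue), 1.0),
        alternative=alternative,
        method="Wilcoxon rank-sum (%s)" % ("exact" if exact else "normal approximation"),
    )
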