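"""Rank statistics used for across-cohort method comparisons.

Thin, convention-pinning wrappers around SciPy:

* :func:`mann_whitney_u` reports the U statistic of the *first* sample,
  ``U = #{(i, j): x_i > y_j} + 0.5 * #ties`` — the convention under which
  complete separation in the small direction gives U = 0 and values above
  ``n1 * n2 / 2`` are possible.  Two-sided p-values use the exact null
  distribution for small tie-free problems (``n1 * n2 <= 400``) and the
  tie-corrected normal approximation otherwise.
* :func:`spearman_rho` is Spearman's rank correlation (Pearson correlation
  of average ranks) with the t-approximation p-value.

The conventional significance threshold for these comparisons is 0.01.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "CorrelationResult",
    "mann_whitney_u",
    "spearman_rho",
    "SIGNIFICANCE_THRESHOLD",
]

SIGNIFICANCE_THRESHOLD = 0.01


@dataclasses.dataclass(frozen=True)
class RankTestResult:
    u_statistic: float  # half-integers possible with ties
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U must lie in [0, n1 * n2]")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_THRESHOLD


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    undefined: bool = False


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return np.unique(combined).size < combined.size


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test; U is the first sample's statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    small = x.size * y.size <= 400
    method = "exact" if small and not _has_ties(x, y) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
    )


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman's rank correlation of two paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("paired samples of equal length >= 3 are required")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(rho=math.nan, p_value=math.nan, undefined=True)
    res = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue))
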