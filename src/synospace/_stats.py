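"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mannwhitney_u", "pearson_r"]


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have <= 8 observations and there
    are no ties; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Two-sided Pearson correlation; (nan, nan) if either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("Pearson correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
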