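"""Cohort-level statistics: the paired t-test used for donor-matched comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided paired t-test between donor-matched condition values.

    ``degenerate`` flags zero-variance differences, where t is undefined
    (reported as NaN rather than infinity).
    """

    condition_a: str
    condition_b: str
    paired_differences: tuple[float, ...]
    t_statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def paired_t(values_a, values_b, condition_a: str = "a", condition_b: str = "b") -> ComparisonResult:
    """Two-sided paired t-test on per-donor percentages.

    Pairs are matched by position (one donor per index).  Differences with
    zero variance give an undefined (NaN) statistic, flagged ``degenerate``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return ComparisonResult(
            condition_a, condition_b, tuple(diffs), float("nan"), float("nan"), n, True
        )
    res = sps.ttest_rel(a, b)
    return ComparisonResult(
        condition_a, condition_b, tuple(diffs), float(res.statistic), float(res.pvalue), n
    )
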