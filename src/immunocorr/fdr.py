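"""Multiple-testing control and the univariate group-difference dispatcher.

FDR control uses the two-stage linear step-up procedure of Benjamini,
Krieger & Yekutieli (adaptive FDR): a first linear step-up pass at
q' = q/(1+q) estimates the number of true nulls m0 = m - r1, and a second
pass runs the linear step-up at level q'·m/m0.  At q = 10% this is the
procedure applied to every analysis family in the pipeline.

The group-difference dispatcher follows the conventional decision tree:
Shapiro-Wilk normality per group first (non-normal data go to Mann-Whitney),
then Brown-Forsythe equality of variances (unequal variances go to Welch's t),
otherwise Student's t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class FdrOutcome:
    p_in: tuple[float, ...]
    rejected: tuple[bool, ...]
    q: float
    m0_hat: int
    stage1_rejections: int


def _step_up_count(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the BH linear step-up at the given level."""
    m = p_sorted.size
    crit = level * np.arange(1, m + 1) / m
    passed = np.nonzero(p_sorted <= crit)[0]
    return int(passed[-1] + 1) if passed.size else 0


def bky_two_stage(p: Sequence[float], q: float = 0.10) -> FdrOutcome:
    """Two-stage Benjamini-Krieger-Yekutieli adaptive linear step-up.

    Stage 1: linear step-up at q' = q/(1+q); r1 rejections give
    m0_hat = m - r1.  If r1 = 0, reject nothing; if m0_hat = 0, reject all.
    Stage 2: linear step-up at q'·m/m0_hat; decisions returned in input order.
    """
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p_arr)) or np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")

    m = p_arr.size
    order = np.argsort(p_arr, kind="stable")
    p_sorted = p_arr[order]
    q_prime = q / (1.0 + q)

    r1 = _step_up_count(p_sorted, q_prime)
    m0_hat = m - r1
    rejected_sorted = np.zeros(m, dtype=bool)
    if r1 == 0:
        pass
    elif m0_hat == 0:
        rejected_sorted[:] = True
    else:
        r2 = _step_up_count(p_sorted, q_prime * m / m0_hat)
        rejected_sorted[:r2] = True

    rejected = np.zeros(m, dtype=bool)
    rejected[order] = rejected_sorted
    return FdrOutcome(
        p_in=tuple(float(v) for v in p_arr),
        rejected=tuple(bool(v) for v in rejected),
        q=q,
        m0_hat=int(m0_hat),
        stage1_rejections=int(r1),
    )


def group_difference(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
) -> tuple[str, float, float]:
    """Dispatch a two-group location test by distribution and variance checks.

    Returns ``(test_name, statistic, p)`` where test_name is one of
    "mann-whitney", "welch-t" or "student-t", naming the branch that fired.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs >= 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups constant; no test applicable")

    normal = True
    for v in (a, b):
        if np.ptp(v) == 0 or float(stats.shapiro(v).pvalue) < alpha_normality:
            normal = False
            break
    if not normal:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return "mann-whitney", float(res.statistic), float(res.pvalue)

    # Brown-Forsythe: Levene's test with median centering
    bf_p = float(stats.levene(a, b, center="median").pvalue)
    if bf_p < alpha_variance:
        res = stats.ttest_ind(a, b, equal_var=False)
        return "welch-t", float(res.statistic), float(res.pvalue)
    res = stats.ttest_ind(a, b, equal_var=True)
    return "student-t", float(res.statistic), float(res.pvalue)
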