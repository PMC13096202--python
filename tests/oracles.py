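"""Independent brute-force reference implementations used only by tests.

Each oracle is written directly from the defining construction of the
statistic it checks and shares no code with the package implementation.
"""

import numpy as np
from scipy import stats


def partial_spearman_oracle(x, y, cov) -> float:
    """Partial Spearman by explicit rank vectors and normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.asarray(cov, float).reshape(len(x), -1)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    design = np.column_stack([np.ones(len(x)), cov])
    bx = np.linalg.solve(design.T @ design, design.T @ rx)
    by = np.linalg.solve(design.T @ design, design.T @ ry)
    ex, ey = rx - design @ bx, ry - design @ by
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def bh_step_up_count(p_sorted, level) -> int:
    """Benjamini-Hochberg linear step-up: largest i with p_(i) <= i/m*level."""
    m = len(p_sorted)
    passing = [i + 1 for i in range(m) if p_sorted[i] <= (i + 1) / m * level]
    return max(passing) if passing else 0


def bh_reject(p, level) -> np.ndarray:
    p = np.asarray(p, float)
    order = np.argsort(p)
    r = bh_step_up_count(p[order], level)
    out = np.zeros(p.size, bool)
    out[order[:r]] = True
    return out


def bky_two_stage_reference(p, q) -> np.ndarray:
    """Two-stage adaptive step-up written from its defining inequalities."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ps = p[order]
    q_prime = q / (1 + q)
    r1 = bh_step_up_count(ps, q_prime)
    if r1 == 0:
        rej_sorted = np.zeros(m, bool)
    elif r1 == m:
        rej_sorted = np.ones(m, bool)
    else:
        m0 = m - r1
        r2 = bh_step_up_count(ps, q_prime * m / m0)
        rej_sorted = np.arange(m) < r2
    out = np.zeros(m, bool)
    out[order] = rej_sorted
    return out
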