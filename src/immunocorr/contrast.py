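"""Between-group contrasts of correlations and regression slopes.

Two diagnostic groups (e.g. patients vs controls) each yield a correlation or
a regression slope for the same protein pair; this module quantifies the
difference.  Correlation contrasts use Fisher's z-transformation with
group-specific effective sample sizes; for partial correlations the variance
term is corrected to 1/(n - 3 - k), which reduces to the classical formula at
k = 0.  Slope contrasts fit per-group OLS models and compare the two slopes
with a two-sided Welch t-test using Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .correlation import HubProfile


@dataclass(frozen=True)
class DeltaEntry:
    """Per-protein correlation difference between groups (FEP minus HC)."""

    protein: str
    r_fep: float
    r_hc: float
    delta: float
    z_stat: float
    p: float
    n_fep: int
    n_hc: int
    significant: bool | None = None  # filled after FDR


@dataclass(frozen=True)
class SlopeContrast:
    slope_fep: float
    slope_hc: float
    se_fep: float
    se_hc: float
    t: float
    df: float
    p: float


def fisher_z_contrast(
    r1: float, n1: int, r2: float, n2: int, k_cov: int = 0
) -> tuple[float, float]:
    """Fisher-z statistic and two-sided p for the difference r1 - r2.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3-k) + 1/(n2-3-k)).
    """
    for r, name in ((r1, "r1"), (r2, "r2")):
        if abs(r) >= 1.0:
            raise ValueError(f"{name} = {r}: Fisher transform diverges at |r| = 1")
    for n, name in ((n1, "n1"), (n2, "n2")):
        if n <= k_cov + 3:
            raise ValueError(f"{name} = {n} must exceed k_cov + 3 = {k_cov + 3}")
    se = math.sqrt(1.0 / (n1 - 3 - k_cov) + 1.0 / (n2 - 3 - k_cov))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def delta_profile(
    profile_fep: HubProfile, profile_hc: HubProfile
) -> list[DeltaEntry]:
    """Per-protein Fisher-z contrasts between two aligned hub profiles.

    Each pair uses its own group-specific n_eff and k_cov.  Pairs where either
    group's correlation is unusable yield NaN entries (skipped by FDR).
    """
    if profile_fep.panel != profile_hc.panel:
        only_fep = set(profile_fep.panel) - set(profile_hc.panel)
        only_hc = set(profile_hc.panel) - set(profile_fep.panel)
        raise ValueError(
            f"panel mismatch: only in first profile {sorted(only_fep)}, "
            f"only in second {sorted(only_hc)} (or ordering differs)"
        )
    entries = []
    for prot, res_f, res_h in zip(
        profile_fep.panel, profile_fep.results, profile_hc.results
    ):
        if not (res_f.usable and res_h.usable):
            entries.append(
                DeltaEntry(prot, res_f.r, res_h.r, float("nan"), float("nan"),
                           float("nan"), res_f.n_eff, res_h.n_eff)
            )
            continue
        z, p = fisher_z_contrast(
            res_f.r, res_f.n_eff, res_h.r, res_h.n_eff,
            k_cov=max(res_f.k_cov, res_h.k_cov),
        )
        entries.append(
            DeltaEntry(
                protein=prot,
                r_fep=res_f.r,
                r_hc=res_h.r,
                delta=res_f.r - res_h.r,
                z_stat=z,
                p=p,
                n_fep=res_f.n_eff,
                n_hc=res_h.n_eff,
            )
        )
    return entries


def flag_deltas(entries: list[DeltaEntry], rejected: Sequence[bool]) -> list[DeltaEntry]:
    """Attach FDR rejection flags (aligned with the usable-p subset order)."""
    out, it = [], iter(rejected)
    for e in entries:
        if math.isnan(e.p):
            out.append(replace(e, significant=None))
        else:
            out.append(replace(e, significant=bool(next(it))))
    return out


def _group_slope(
    x: Sequence[float], y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None,
) -> tuple[float, float, int]:
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if covariates is None:
        cov = np.empty((xv.size, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        cov = cov.reshape(xv.size, -1)
    mask = np.isfinite(xv) & np.isfinite(yv)
    if cov.shape[1]:
        mask &= np.all(np.isfinite(cov), axis=1)
    xv, yv, cov = xv[mask], yv[mask], cov[mask]
    # drop constant covariates (collinear with the intercept)
    if cov.shape[1]:
        cov = cov[:, np.ptp(cov, axis=0) > 0]
    if xv.size < cov.shape[1] + 3:
        raise ValueError(f"too few complete cases ({xv.size}) for slope fit")
    if np.ptp(xv) == 0:
        raise ValueError("predictor constant within group")
    design = sm.add_constant(np.column_stack([xv] + ([cov] if cov.shape[1] else [])))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design in slope fit")
    fit = sm.OLS(yv, design).fit()
    return float(fit.params[1]), float(fit.bse[1]), int(fit.df_resid)


def slope_contrast(
    x_fep: Sequence[float], y_fep: Sequence[float],
    x_hc: Sequence[float], y_hc: Sequence[float],
    covariates_fep: pd.DataFrame | np.ndarray | None = None,
    covariates_hc: pd.DataFrame | np.ndarray | None = None,
) -> SlopeContrast:
    """Compare the slope of y on x between groups via a Welch t-test.

    Each group is fitted by OLS of y on intercept + x + covariates; the
    slope on x and its standard error feed
    t = (b_fep - b_hc) / sqrt(se_fep^2 + se_hc^2) with Satterthwaite df.
    """
    b1, se1, df1 = _group_slope(x_fep, y_fep, covariates_fep)
    b2, se2, df2 = _group_slope(x_hc, y_hc, covariates_hc)
    var = se1**2 + se2**2
    t = (b1 - b2) / math.sqrt(var) if var > 0 else 0.0
    if var > 0:
        df = var**2 / (se1**4 / df1 + se2**4 / df2)
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        df, p = float(df1 + df2), 1.0
    return SlopeContrast(
        slope_fep=b1, slope_hc=b2, se_fep=se1, se_hc=se2, t=t, df=df, p=p
    )


def compare_distributions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) on two sets of values,
    typically two groups' correlation coefficients."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both inputs must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
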