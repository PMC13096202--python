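"""Plain and covariate-adjusted (partial) correlation engine.

Implements the association machinery used throughout the package: Pearson or
Spearman coefficients with normality-gated method selection (Shapiro-Wilk),
pairwise deletion of missing values, and partial correlations computed by
residualizing on covariates.

Partial Spearman is defined as rank-then-residualize: both variables are
rank-transformed (average ranks for ties) over the complete cases of the
(x, y, covariates) tuple, residualized on an intercept plus the covariates by
ordinary least squares, and the Pearson correlation of the residuals is
returned.  The p-value uses the t approximation with df = n - 2 - k, where k
counts the covariates actually fitted.  Covariate columns that are constant on
the complete cases (e.g. a medication flag in an unmedicated control group)
are dropped before fitting and k is decremented accordingly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Method = Literal["pearson", "spearman"]

#: minimum complete pairs for an unadjusted correlation; a partial
#: correlation additionally requires one more case per covariate.
MIN_PAIRS = 4


def fisher_z(r: float) -> float:
    """atanh(r); returns signed infinity at |r| = 1."""
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r)
    return math.atanh(r)


@dataclass(frozen=True)
class CorrelationResult:
    """One pairwise association.

    Attributes
    ----------
    r : correlation coefficient in [-1, 1] (NaN if unusable).
    fisher_z : atanh(r); +/-inf at |r| = 1.
    p : two-sided p-value.
    n_eff : number of subjects used after deletion.
    k_cov : number of covariates actually adjusted for (after constant-drop).
    method : "pearson" or "spearman".
    usable : False when fewer than k_cov + 4 complete cases were available.
    dropped_covariates : names of covariate columns removed as constant.
    """

    r: float
    fisher_z: float
    p: float
    n_eff: int
    k_cov: int
    method: Method
    usable: bool = True
    dropped_covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class MethodDecision:
    """Outcome of the normality gate used to pick the correlation method."""

    shapiro_p_x: float
    shapiro_p_y: float
    chosen: Method


@dataclass
class HubProfile:
    """Correlations from one hub protein to every protein of a panel,
    within one diagnostic group and compartment."""

    hub: str
    group: str
    panel: list[str]
    results: list[CorrelationResult]
    compartment: str = ""

    def __post_init__(self) -> None:
        if len(self.panel) != len(self.results):
            raise ValueError("panel and results must have equal length")

    @property
    def r_values(self) -> np.ndarray:
        return np.array([res.r for res in self.results], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hub": self.hub,
                "group": self.group,
                "compartment": self.compartment,
                "protein": self.panel,
                "r": [res.r for res in self.results],
                "fisher_z": [res.fisher_z for res in self.results],
                "p": [res.p for res in self.results],
                "n_eff": [res.n_eff for res in self.results],
                "k_cov": [res.k_cov for res in self.results],
                "method": [res.method for res in self.results],
                "usable": [res.usable for res in self.results],
            }
        )


def _as_float_array(v: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    return np.asarray(v, dtype=float).ravel()


def decide_method(
    x: Sequence[float],
    y: Sequence[float],
    alpha_normality: float = 0.05,
) -> MethodDecision:
    """Choose Pearson vs Spearman from per-vector Shapiro-Wilk tests.

    Pearson is used only when both vectors look normal (both Shapiro-Wilk
    p-values >= ``alpha_normality``); otherwise Spearman.

    Raises
    ------
    ValueError
        If either vector has fewer than 3 non-missing values or is constant
        (the Shapiro-Wilk statistic is undefined there).
    """
    ps = []
    for name, v in (("x", x), ("y", y)):
        vv = _as_float_array(v)
        vv = vv[np.isfinite(vv)]
        if vv.size < 3:
            raise ValueError(f"{name}: need >= 3 non-missing values for Shapiro-Wilk")
        if np.ptp(vv) == 0:
            raise ValueError(f"{name}: constant vector; Shapiro-Wilk undefined")
        ps.append(float(stats.shapiro(vv).pvalue))
    chosen: Method = (
        "pearson" if (ps[0] >= alpha_normality and ps[1] >= alpha_normality) else "spearman"
    )
    return MethodDecision(shapiro_p_x=ps[0], shapiro_p_y=ps[1], chosen=chosen)


def _unusable(method: Method, n_eff: int, k_cov: int = 0) -> CorrelationResult:
    return CorrelationResult(
        r=float("nan"),
        fisher_z=float("nan"),
        p=float("nan"),
        n_eff=n_eff,
        k_cov=k_cov,
        method=method,
        usable=False,
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Method = "spearman",
) -> CorrelationResult:
    """Unadjusted correlation on complete pairs (pairwise deletion).

    Fewer than 4 complete pairs yields an unusable flagged result rather
    than an exception, so profile-level callers can skip and count.
    """
    xv, yv = _as_float_array(x), _as_float_array(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    mask = np.isfinite(xv) & np.isfinite(yv)
    n_eff = int(mask.sum())
    if n_eff < MIN_PAIRS:
        return _unusable(method, n_eff)
    xs, ys = xv[mask], yv[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return _unusable(method, n_eff)
    if method == "pearson":
        res = stats.pearsonr(xs, ys)
    elif method == "spearman":
        res = stats.spearmanr(xs, ys)
    else:
        raise ValueError(f"unknown method: {method!r}")
    r = float(res.statistic)
    return CorrelationResult(
        r=r,
        fisher_z=fisher_z(r),
        p=float(res.pvalue),
        n_eff=n_eff,
        k_cov=0,
        method=method,
    )


def _drop_constant_columns(
    cov: np.ndarray, names: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    keep, dropped = [], []
    for j in range(cov.shape[1]):
        if np.ptp(cov[:, j]) == 0:
            dropped.append(names[j])
        else:
            keep.append(j)
    return cov[:, keep], [names[j] for j in keep], dropped


def _check_design_rank(design: np.ndarray, names: list[str]) -> None:
    # intercept is column 0; names cover the covariate columns
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        collinear = []
        cur = design[:, :1]
        for j, name in enumerate(names, start=1):
            cand = np.hstack([cur, design[:, j : j + 1]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                collinear.append(name)
            else:
                cur = cand
        raise ValueError(
            f"covariate design rank-deficient; collinear columns: {collinear}"
        )


def partial_correlate(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    method: Method = "spearman",
    covariate_names: Sequence[str] | None = None,
) -> CorrelationResult:
    """Partial correlation of x and y given covariates.

    Complete cases are taken listwise across the (x, y, covariates) tuple;
    deletion is pairwise only across *different* correlations.  Constant
    covariate columns are dropped (with a logged warning) before fitting.

    With no covariates this reduces exactly to :func:`correlate`.
    """
    xv, yv = _as_float_array(x), _as_float_array(y)
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")

    if covariates is None:
        cov_arr = np.empty((xv.size, 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        cov_arr = covariates.to_numpy(dtype=float)
        names = [str(c) for c in covariates.columns]
    else:
        cov_arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov_arr.shape[0] != xv.size and cov_arr.shape[1] == xv.size:
            cov_arr = cov_arr.T
        names = (
            [str(n) for n in covariate_names]
            if covariate_names is not None
            else [f"cov{j}" for j in range(cov_arr.shape[1])]
        )
    if cov_arr.shape[0] != xv.size:
        raise ValueError("covariate rows must match x/y length")

    mask = np.isfinite(xv) & np.isfinite(yv)
    if cov_arr.shape[1]:
        mask &= np.all(np.isfinite(cov_arr), axis=1)
    n_eff = int(mask.sum())

    cov_cc = cov_arr[mask]
    cov_cc, kept_names, dropped = _drop_constant_columns(cov_cc, names)
    if dropped:
        logger.warning("dropping constant covariate column(s): %s", dropped)
    k = cov_cc.shape[1]

    if k == 0:
        base = correlate(xv[mask], yv[mask], method=method)
        return CorrelationResult(
            r=base.r,
            fisher_z=base.fisher_z,
            p=base.p,
            n_eff=base.n_eff,
            k_cov=0,
            method=method,
            usable=base.usable,
            dropped_covariates=tuple(dropped),
        )

    if n_eff < k + MIN_PAIRS:
        return _unusable(method, n_eff, k_cov=k)

    xs, ys = xv[mask], yv[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return _unusable(method, n_eff, k_cov=k)
    if method == "spearman":
        xs = stats.rankdata(xs)
        ys = stats.rankdata(ys)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")

    design = np.column_stack([np.ones(n_eff), cov_cc])
    _check_design_rank(design, kept_names)
    beta, *_ = np.linalg.lstsq(design, np.column_stack([xs, ys]), rcond=None)
    resid = np.column_stack([xs, ys]) - design @ beta
    rx, ry = resid[:, 0], resid[:, 1]
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return _unusable(method, n_eff, k_cov=k)
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))

    df = n_eff - 2 - k
    if df <= 0 or abs(r) >= 1.0:
        p = 0.0 if abs(r) >= 1.0 else float("nan")
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(
        r=r,
        fisher_z=fisher_z(r),
        p=p,
        n_eff=n_eff,
        k_cov=k,
        method=method,
        dropped_covariates=tuple(dropped),
    )


def hub_profile(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None,
    hub: str,
    panel: Sequence[str],
    group_labels: pd.Series | None = None,
    group: str | None = None,
    method_policy: str = "spearman",
    alpha_normality: float = 0.05,
    compartment: str = "",
) -> HubProfile:
    """Correlation profile from a hub protein to every panel protein.

    Parameters
    ----------
    proteins : subject x protein DataFrame (hub and panel columns).
    covariates : aligned covariate DataFrame, or None for zero-order profiles.
    group_labels, group : restrict to subjects whose label equals ``group``.
    method_policy : "spearman", "pearson", or "auto" (per-pair Shapiro gate).
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    missing = [p for p in ([hub] + panel) if p not in proteins.columns]
    if missing:
        raise KeyError(f"protein(s) absent from data: {missing}")

    if covariates is not None:
        covariates = covariates.reindex(proteins.index)
    if group_labels is not None and group is not None:
        sel = (group_labels.reindex(proteins.index) == group).to_numpy()
        proteins = proteins.loc[sel]
        if covariates is not None:
            covariates = covariates.loc[sel]
    group_name = group if group is not None else ""

    hub_vals = proteins[hub]
    results = []
    for prot in panel:
        x, y = hub_vals, proteins[prot]
        if method_policy == "auto":
            method = decide_method(x, y, alpha_normality).chosen
        elif method_policy in ("spearman", "pearson"):
            method = method_policy  # type: ignore[assignment]
        else:
            raise ValueError(f"unknown method_policy: {method_policy!r}")
        results.append(partial_correlate(x, y, covariates, method=method))
    return HubProfile(
        hub=hub,
        group=group_name,
        panel=panel,
        results=results,
        compartment=compartment,
    )
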