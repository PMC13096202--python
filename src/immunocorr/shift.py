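"""Permutation tests for global shifts of hub-panel correlation profiles.

The central inference of the package: given a hub protein (e.g. complement
C4A) and a panel of inflammation proteins, each diagnostic group yields a
profile of covariate-adjusted partial Spearman correlations.  Two statistics
summarise how the patient profile differs from the control profile:

* directional — mean over proteins of (r_patient - r_control), detecting a
  consistent signed shift of the whole profile;
* absolute — mean over proteins of |r_patient - r_control|, detecting a
  change in association magnitude regardless of sign.

Significance comes from permuting diagnosis labels across subjects (each
subject's covariates and protein values travel together; only the label
moves) and recomputing the full profile pipeline per permutation.  Empirical
p-values use the add-one correction (1 + #{null >= observed}) / (n_perm + 1),
so they can never be exactly zero.  The directional test is one-sided toward
a positive shift by default (flip with ``alternative="less"``); the absolute
test always uses the upper tail of the magnitude statistic.

A z-score — the observed statistic standardised against the permutation-null
mean and SD — is reported alongside the empirical p so both conventions are
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import MIN_PAIRS, HubProfile, hub_profile

logger = logging.getLogger(__name__)

Mode = Literal["directional", "absolute"]

#: fraction of protein-by-permutation cells allowed to be skipped (too few
#: complete cases) before the test aborts with diagnostics.
MAX_SKIP_FRACTION = 0.10


@dataclass(frozen=True)
class ShiftResult:
    """Outcome of one permutation profile-shift test.

    ``observed_raw`` is the statistic as computed on the real labels;
    ``observed`` equals it for the directional mode and is centered by the
    permutation-null mean for the absolute mode (whose null expectation is
    positive).  ``p_emp`` uses the add-one correction on the tail of the raw
    statistic.
    """

    hub: str
    mode: Mode
    observed: float
    observed_raw: float
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    n_perm: int
    seed: int
    alternative: str = "greater"
    n_skipped_cells: int = 0
    compartment: str = ""


def observed_statistic(
    profile_fep: HubProfile, profile_hc: HubProfile, mode: Mode
) -> float:
    """Directional or absolute mean profile difference (FEP minus HC)."""
    if profile_fep.panel != profile_hc.panel:
        raise ValueError("panel mismatch between profiles")
    delta = profile_fep.r_values - profile_hc.r_values
    delta = delta[np.isfinite(delta)]
    if delta.size == 0:
        raise ValueError("no usable protein pairs in either profile")
    if mode == "directional":
        return float(np.mean(delta))
    if mode == "absolute":
        return float(np.mean(np.abs(delta)))
    raise ValueError(f"unknown mode: {mode!r}")


def _rank_columns(a: np.ndarray) -> np.ndarray:
    """Average ranks per column (vectorised scipy rankdata)."""
    return stats.rankdata(a, axis=0)


def _profile_pair_fast(
    values: np.ndarray,
    design: np.ndarray,
    is_fep: np.ndarray,
    spearman: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Hub-panel partial correlation profiles for both groups at once.

    ``values`` is (n, 1 + p) with the hub in column 0 and the panel after it;
    ``design`` is (n, 1 + k) with an intercept column first.  All entries must
    be finite (the fast path precondition).  Returns (r_fep, r_hc, n_skipped).
    Within each group, design columns constant on that group's rows are
    dropped before projection (they are collinear with the intercept).
    """
    out = []
    skipped = 0
    p = values.shape[1] - 1
    for sel in (is_fep, ~is_fep):
        rows = values[sel]
        n = rows.shape[0]
        x = design[sel]
        keep = [0] + [j for j in range(1, x.shape[1]) if np.ptp(x[:, j]) > 0]
        x = x[:, keep]
        k = x.shape[1] - 1
        if n < k + MIN_PAIRS:
            out.append(np.full(p, np.nan))
            skipped += p
            continue
        r_mat = _rank_columns(rows) if spearman else rows
        q, _ = np.linalg.qr(x)
        resid = r_mat - q @ (q.T @ r_mat)
        norms = np.sqrt(np.einsum("ij,ij->j", resid, resid))
        hub_res = resid[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (hub_res @ resid[:, 1:]) / (norms[0] * norms[1:])
        bad = ~np.isfinite(r)
        skipped += int(bad.sum())
        out.append(np.clip(r, -1.0, 1.0))
    return out[0], out[1], skipped


def _statistics_from_profiles(
    r_fep: np.ndarray, r_hc: np.ndarray
) -> tuple[float, float]:
    """(directional, absolute) statistics, NaN-pairs excluded."""
    delta = r_fep - r_hc
    delta = delta[np.isfinite(delta)]
    if delta.size == 0:
        return float("nan"), float("nan")
    return float(np.mean(delta)), float(np.mean(np.abs(delta)))


def _prepare_arrays(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None,
    group_labels: pd.Series,
    hub: str,
    panel: Sequence[str],
    fep_label: str,
    hc_label: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    panel = list(panel)
    cols = [hub] + panel
    missing = [c for c in cols if c not in proteins.columns]
    if missing:
        raise KeyError(f"protein(s) absent from data: {missing}")
    labels = group_labels.reindex(proteins.index).to_numpy()
    keep = (labels == fep_label) | (labels == hc_label)
    values = proteins.loc[keep, cols].to_numpy(dtype=float)
    is_fep = labels[keep] == fep_label
    if covariates is not None:
        cov = covariates.reindex(proteins.index).loc[keep].to_numpy(dtype=float)
    else:
        cov = np.empty((values.shape[0], 0))
    design = np.column_stack([np.ones(values.shape[0]), cov])
    # drop subjects with missing covariates: a partial correlation cannot use them
    cov_ok = np.all(np.isfinite(design), axis=1)
    return values[cov_ok], design[cov_ok], is_fep[cov_ok]


def _null_moments(null: np.ndarray) -> tuple[float, float]:
    return float(np.mean(null)), float(np.std(null, ddof=1))


def _empirical_p(observed: float, null: np.ndarray, alternative: str) -> float:
    if alternative == "less":
        count = int(np.sum(null <= observed))
    else:
        count = int(np.sum(null >= observed))
    return (1.0 + count) / (null.size + 1.0)


def permutation_shift_test(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None,
    group_labels: pd.Series,
    hub: str,
    panel: Sequence[str],
    mode: Mode = "directional",
    n_perm: int = 10_000,
    seed: int = 0,
    method_policy: str = "spearman",
    fep_label: str = "FEP",
    hc_label: str = "HC",
    alternative: str = "greater",
    compartment: str = "",
) -> ShiftResult:
    """Permutation test of a profile-level correlation shift for one hub.

    Group labels are permuted across subjects (covariates travel with their
    subject) and the full per-group partial-correlation profile is recomputed
    for every permutation.  Deterministic under ``seed``.
    """
    res_d, res_a = _shift_test_both(
        proteins, covariates, group_labels, hub, panel,
        n_perm=n_perm, seed=seed, method_policy=method_policy,
        fep_label=fep_label, hc_label=hc_label, alternative=alternative,
        compartment=compartment,
    )
    return res_d if mode == "directional" else res_a


def directional_and_absolute(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None,
    group_labels: pd.Series,
    hub: str,
    panel: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    method_policy: str = "spearman",
    fep_label: str = "FEP",
    hc_label: str = "HC",
    alternative: str = "greater",
    compartment: str = "",
) -> tuple[ShiftResult, ShiftResult]:
    """Both shift modes from the same permutation stream (same label
    shuffles), so the two results are directly comparable."""
    return _shift_test_both(
        proteins, covariates, group_labels, hub, panel,
        n_perm=n_perm, seed=seed, method_policy=method_policy,
        fep_label=fep_label, hc_label=hc_label, alternative=alternative,
        compartment=compartment,
    )


def _shift_test_both(
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None,
    group_labels: pd.Series,
    hub: str,
    panel: Sequence[str],
    n_perm: int,
    seed: int,
    method_policy: str,
    fep_label: str,
    hc_label: str,
    alternative: str,
    compartment: str,
) -> tuple[ShiftResult, ShiftResult]:
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if mode_err := (method_policy not in ("spearman", "pearson")):
        raise ValueError(f"method_policy must be spearman or pearson: {method_policy!r}")
    del mode_err
    if alternative not in ("greater", "less"):
        raise ValueError(f"alternative must be 'greater' or 'less': {alternative!r}")
    panel = list(panel)
    values, design, is_fep = _prepare_arrays(
        proteins, covariates, group_labels, hub, panel, fep_label, hc_label
    )
    n_sub = values.shape[0]
    if is_fep.sum() < MIN_PAIRS or (~is_fep).sum() < MIN_PAIRS:
        raise ValueError("each group needs enough subjects for partial correlations")
    spearman = method_policy == "spearman"

    complete = bool(np.all(np.isfinite(values)))
    if complete:
        def profiles(lbl: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
            return _profile_pair_fast(values, design, lbl, spearman)
    else:
        # general path: per-protein complete cases (slower; used with missingness)
        def profiles(lbl: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
            return _profile_pair_masked(values, design, lbl, spearman)

    r_fep, r_hc, skipped = profiles(is_fep)
    obs_dir, obs_abs = _statistics_from_profiles(r_fep, r_hc)

    rng = np.random.default_rng(seed)
    null_dir = np.empty(n_perm)
    null_abs = np.empty(n_perm)
    total_cells = n_perm * len(panel)
    total_skipped = skipped
    for b in range(n_perm):
        perm = rng.permutation(n_sub)
        rf, rh, sk = profiles(is_fep[perm])
        total_skipped += sk
        null_dir[b], null_abs[b] = _statistics_from_profiles(rf, rh)

    if total_skipped > MAX_SKIP_FRACTION * total_cells:
        raise RuntimeError(
            f"{total_skipped}/{total_cells} protein-permutation cells skipped "
            f"(> {MAX_SKIP_FRACTION:.0%}); data too sparse for a stable "
            f"permutation null — check missingness and group sizes"
        )
    if total_skipped:
        logger.info("shift test %s: %d skipped cells", hub, total_skipped)

    results = []
    for mode, obs, null in (
        ("directional", obs_dir, null_dir),
        ("absolute", obs_abs, null_abs),
    ):
        null_ok = null[np.isfinite(null)]
        mean, sd = _null_moments(null_ok)
        alt = alternative if mode == "directional" else "greater"
        p_emp = _empirical_p(obs, null_ok, alt)
        z = (obs - mean) / sd if sd > 0 else float("nan")
        observed = obs if mode == "directional" else obs - mean
        results.append(
            ShiftResult(
                hub=hub, mode=mode, observed=observed, observed_raw=obs,
                null_mean=mean, null_sd=sd, z=z, p_emp=p_emp,
                n_perm=n_perm, seed=seed, alternative=alt,
                n_skipped_cells=total_skipped, compartment=compartment,
            )
        )
    return results[0], results[1]


def _profile_pair_masked(
    values: np.ndarray,
    design: np.ndarray,
    is_fep: np.ndarray,
    spearman: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Missing-tolerant path: per protein, complete cases of (hub, protein,
    covariates) within each group; listwise within the tuple, pairwise across
    proteins."""
    p = values.shape[1] - 1
    out = []
    skipped = 0
    hub_col = values[:, 0]
    for sel in (is_fep, ~is_fep):
        r_vec = np.full(p, np.nan)
        for j in range(1, p + 1):
            mask = sel & np.isfinite(hub_col) & np.isfinite(values[:, j])
            x = design[mask]
            keep = [0] + [c for c in range(1, x.shape[1]) if np.ptp(x[:, c]) > 0]
            x = x[:, keep]
            k = x.shape[1] - 1
            n = int(mask.sum())
            if n < k + MIN_PAIRS:
                skipped += 1
                continue
            pair = values[mask][:, [0, j]]
            if spearman:
                pair = _rank_columns(pair)
            q, _ = np.linalg.qr(x)
            resid = pair - q @ (q.T @ pair)
            denom = float(np.linalg.norm(resid[:, 0]) * np.linalg.norm(resid[:, 1]))
            if denom == 0:
                skipped += 1
                continue
            r_vec[j - 1] = np.clip(float(resid[:, 0] @ resid[:, 1]) / denom, -1, 1)
        out.append(r_vec)
    return out[0], out[1], skipped
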