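"""Synthetic two-group, two-compartment protein cohort generator.

Emulates a case-control CSF/plasma proteomics study: two diagnostic groups
(healthy controls, HC, and first-episode psychosis patients, FEP), a small
set of complement "hub" proteins measured in CSF (C4A, C4B, C1QA) and a
48-protein inflammation panel measured in both CSF and plasma on a log2
relative-abundance scale, plus age/sex/BMI/medication covariates and PANSS
symptom scores for patients.

The latent model is a Gaussian copula on the log2 scale: per group a target
correlation matrix over (hubs + panel) is assembled from prescribed hub-panel
mean correlations (with per-protein jitter), hub-hub correlations and a panel
base correlation, projected to the nearest valid correlation matrix
(eigenvalue clipping followed by diagonal renormalization), and multivariate
normal latents are drawn from it.  Spearman-based downstream statistics are
invariant to monotone marginal transforms, so Gaussian marginals suffice.

Default parameter values follow the emulated study design: 90 HC / 113 FEP
subjects, 48 panel proteins, C4A negative-leaning hub correlations in HC
that shift positive in FEP, C4B/C1QA positive in both groups, weak CSF-plasma
coupling, and mild completely-at-random missingness.  An optional
detection-limit-like MNAR mode (missingness probability increasing at low
abundance) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

GROUP_HC = "HC"
GROUP_FEP = "FEP"
DEFAULT_HUBS = ("C4A", "C4B", "C1QA")

#: hub-hub correlation targets per group, from the emulated study design
DEFAULT_HUB_HUB_HC = {("C4A", "C1QA"): 0.41, ("C4B", "C1QA"): 0.48, ("C4A", "C4B"): 0.14}
DEFAULT_HUB_HUB_FEP = {("C4A", "C1QA"): 0.09, ("C4B", "C1QA"): 0.475, ("C4A", "C4B"): 0.13}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Correlation targets are on the latent (Gaussian copula) scale and must
    lie in (-1, 1); realized correlations differ slightly after the
    positive-semidefinite projection and residual noise.
    """

    n_hc: int = 90
    n_fep: int = 113
    n_panel: int = 48
    hub_names: tuple[str, ...] = DEFAULT_HUBS
    # per-hub target correlation to the panel: a scalar mean, or a length-
    # n_panel sequence of per-protein targets
    hub_panel_corr_hc: Mapping[str, float | tuple[float, ...]] = field(
        default_factory=lambda: {"C4A": -0.15, "C4B": 0.25, "C1QA": 0.25}
    )
    hub_panel_corr_fep: Mapping[str, float | tuple[float, ...]] = field(
        default_factory=lambda: {"C4A": 0.20, "C4B": 0.15, "C1QA": 0.25}
    )
    hub_hub_corr_hc: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_HUB_HUB_HC)
    )
    hub_hub_corr_fep: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_HUB_HUB_FEP)
    )
    panel_base_corr: float = 0.25
    corr_jitter: float = 0.08
    cross_compartment_corr: float = 0.10
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.10, "sex": 0.10, "bmi": 0.05, "medication": 0.15}
    )
    missing_rate: float = 0.02
    noise_sd: float = 0.25
    olink_n_hc: int | None = None
    olink_n_fep: int | None = None
    mnar: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_hc < 4 or self.n_fep < 4:
            raise ValueError("n_hc and n_fep must be >= 4")
        if self.n_panel < 1:
            raise ValueError("n_panel must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        targets: list[float] = [self.panel_base_corr, self.cross_compartment_corr]
        targets += list(self.hub_hub_corr_hc.values())
        targets += list(self.hub_hub_corr_fep.values())
        for m in (self.hub_panel_corr_hc, self.hub_panel_corr_fep):
            for v in m.values():
                arr = np.atleast_1d(np.asarray(v, dtype=float))
                if arr.size not in (1, self.n_panel):
                    raise ValueError(
                        f"hub-panel target length {arr.size} != n_panel {self.n_panel}"
                    )
                targets += arr.tolist()
        for t in targets:
            if not (-1.0 < float(t) < 1.0):
                raise ValueError(f"correlation target {t} outside (-1, 1)")
        for hub in self.hub_names:
            for m in (self.hub_panel_corr_hc, self.hub_panel_corr_fep):
                if hub not in m:
                    raise ValueError(f"no hub-panel target for hub {hub!r}")
        if self.corr_jitter < 0 or self.noise_sd < 0:
            raise ValueError("corr_jitter and noise_sd must be non-negative")
        for name, n_sub in (("olink_n_hc", self.olink_n_hc), ("olink_n_fep", self.olink_n_fep)):
            if n_sub is not None and not (4 <= n_sub):
                raise ValueError(f"{name} must be >= 4 when set")

    @property
    def panel_names(self) -> list[str]:
        return [f"INF{i + 1:02d}" for i in range(self.n_panel)]

    @property
    def all_proteins(self) -> list[str]:
        return list(self.hub_names) + self.panel_names


@dataclass
class ProteinMatrix:
    """Subjects x proteins, one compartment, log2-scale levels."""

    values: pd.DataFrame  # index: subject_id, columns: protein names
    compartment: str
    group: pd.Series  # per-subject group label, aligned with values.index

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate subject_ids: {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate protein names")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("protein values must be finite or missing")
        if not self.group.index.equals(self.values.index):
            raise ValueError("group labels not aligned with subject index")


@dataclass
class Cohort:
    csf: ProteinMatrix
    plasma: ProteinMatrix
    covariates: pd.DataFrame  # age, sex (F=0/M=1), bmi, medication, group
    clinical: pd.DataFrame    # FEP subjects only: panss_* columns
    config: SimConfig


def project_to_correlation(a: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Nearest-PSD correlation matrix by eigenvalue clipping at zero
    followed by renormalization to unit diagonal (iterated to convergence)."""
    m = np.asarray(a, dtype=float)
    m = (m + m.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(m)
        if w[0] >= -1e-12:
            break
        m = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.diag(m).copy()
        if np.any(d <= 0):
            raise ValueError(
                "infeasible correlation specification: zero diagonal after projection"
            )
        scale = 1.0 / np.sqrt(d)
        m = m * np.outer(scale, scale)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
    else:
        raise ValueError("PSD projection did not converge")
    return m


def build_target_correlation(config: SimConfig, group: str) -> np.ndarray:
    """Target correlation matrix over (hubs + panel) for one group.

    Hub-panel entries equal the group's target mean plus a per-protein jitter
    (deterministic in the config seed), panel-panel entries equal the panel
    base correlation, hub-hub entries come from the group's hub-hub map; the
    raw matrix is then projected to the nearest valid correlation matrix.
    """
    config.validate()
    if group == GROUP_HC:
        hub_targets, hub_hub = config.hub_panel_corr_hc, config.hub_hub_corr_hc
        stream = 0
    elif group == GROUP_FEP:
        hub_targets, hub_hub = config.hub_panel_corr_fep, config.hub_hub_corr_fep
        stream = 1
    else:
        raise ValueError(f"unknown group {group!r}")

    hubs = list(config.hub_names)
    h, p = len(hubs), config.n_panel
    m = h + p
    c = np.full((m, m), config.panel_base_corr)
    c[:h, :h] = 0.0
    for (a, b), r in hub_hub.items():
        ia, ib = hubs.index(a), hubs.index(b)
        c[ia, ib] = c[ib, ia] = r
    rng = np.random.default_rng([int(config.seed), 7, stream])
    for i, hub in enumerate(hubs):
        jitter = rng.normal(0.0, config.corr_jitter, size=p) if config.corr_jitter else 0.0
        base = np.atleast_1d(np.asarray(hub_targets[hub], dtype=float))
        if base.size == 1:
            base = np.full(p, base[0])
        row = np.clip(base + jitter, -0.99, 0.99)
        c[i, h:] = row
        c[h:, i] = row
    np.fill_diagonal(c, 1.0)
    return project_to_correlation(c)


def _factor(corr: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def _draw_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in ((GROUP_HC, config.n_hc), (GROUP_FEP, config.n_fep)):
        if group == GROUP_HC:
            age = rng.normal(37.7, 14.2, n)
            sex = (rng.random(n) < 48 / 90).astype(int)  # M=1
            med = np.zeros(n, dtype=int)
        else:
            age = rng.normal(31.9, 10.0, n)
            sex = (rng.random(n) < 72 / 113).astype(int)
            med = (rng.random(n) < 77 / 113).astype(int)
        age = np.clip(age, 18.0, None)
        bmi = np.clip(rng.normal(24.7, 4.0, n), 15.0, None)
        ids = [f"{group}{i + 1:03d}" for i in range(n)]
        rows.append(
            pd.DataFrame(
                {"age": age, "sex": sex, "bmi": bmi, "medication": med, "group": group},
                index=pd.Index(ids, name="subject_id"),
            )
        )
    return pd.concat(rows)


_PANSS_SCALES = {
    "panss_positive": (17.6, 6.1, 7, 49),
    "panss_negative": (16.5, 6.6, 7, 49),
    "panss_general": (36.0, 10.5, 16, 112),
}


def _draw_clinical(ids: pd.Index, rng: np.random.Generator) -> pd.DataFrame:
    data = {}
    for name, (mean, sd, lo, hi) in _PANSS_SCALES.items():
        data[name] = np.clip(np.round(rng.normal(mean, sd, len(ids))), lo, hi).astype(int)
    return pd.DataFrame(data, index=ids)


def _apply_missing(
    values: np.ndarray, rate: float, rng: np.random.Generator, mnar: bool
) -> np.ndarray:
    if rate <= 0:
        return values
    out = values.copy()
    if mnar:
        # detection-limit flavour: missingness odds rise at low abundance
        z = stats.zscore(values, axis=0, nan_policy="omit")
        prob = np.clip(rate * np.exp(-z), 0.0, 0.95)
        prob *= rate / prob.mean()
        mask = rng.random(values.shape) < np.clip(prob, 0.0, 0.95)
    else:
        mask = rng.random(values.shape) < rate
    out[mask] = np.nan
    return out


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full two-compartment cohort; bit-identical under a fixed config."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 11])
    covs = _draw_covariates(config, rng)
    proteins = config.all_proteins
    h = len(config.hub_names)
    m = len(proteins)
    rho = float(config.cross_compartment_corr)

    protein_mean = rng.normal(5.0, 1.0, m)

    csf_parts, plasma_parts = [], []
    for group, n in ((GROUP_HC, config.n_hc), (GROUP_FEP, config.n_fep)):
        corr = build_target_correlation(config, group)
        fac = _factor(corr)
        z_csf = rng.standard_normal((n, m)) @ fac.T
        z_other = rng.standard_normal((n, m)) @ fac.T
        z_plasma = rho * z_csf + np.sqrt(1.0 - rho**2) * z_other
        csf_parts.append(z_csf)
        plasma_parts.append(z_plasma)
    z_csf = np.vstack(csf_parts)
    z_plasma = np.vstack(plasma_parts)

    # shared covariate loadings induce confounding across all proteins
    cov_effect = np.zeros(len(covs))
    for name, loading in config.covariate_effects.items():
        col = covs[name].to_numpy(dtype=float)
        sd = col.std()
        if sd > 0:
            col = (col - col.mean()) / sd
        cov_effect = cov_effect + float(loading) * col
    z_csf = z_csf + cov_effect[:, None]
    z_plasma = z_plasma + cov_effect[:, None]

    if config.noise_sd > 0:
        z_csf = z_csf + rng.normal(0.0, config.noise_sd, z_csf.shape)
        z_plasma = z_plasma + rng.normal(0.0, config.noise_sd, z_plasma.shape)

    csf_vals = z_csf + protein_mean
    plasma_vals = z_plasma[:, h:] + protein_mean[h:]

    csf_vals = _apply_missing(csf_vals, config.missing_rate, rng, config.mnar)
    plasma_vals = _apply_missing(plasma_vals, config.missing_rate, rng, config.mnar)

    csf_df = pd.DataFrame(csf_vals, index=covs.index, columns=proteins)
    plasma_df = pd.DataFrame(plasma_vals, index=covs.index, columns=proteins[h:])

    # emulate partial assay coverage: panel measured only in a subject subset,
    # drawn independently per compartment
    for df, n_sub_cfg, cols in (
        (csf_df, (config.olink_n_hc, config.olink_n_fep), config.panel_names),
        (plasma_df, (config.olink_n_hc, config.olink_n_fep), list(plasma_df.columns)),
    ):
        for group, n_sub in zip((GROUP_HC, GROUP_FEP), n_sub_cfg):
            if n_sub is None:
                continue
            ids = covs.index[covs["group"] == group]
            n_sub = min(n_sub, len(ids))
            chosen = rng.choice(len(ids), size=n_sub, replace=False)
            excluded = ids.difference(ids[chosen])
            df.loc[excluded, cols] = np.nan

    group_series = covs["group"]
    clinical = _draw_clinical(covs.index[covs["group"] == GROUP_FEP], rng)
    return Cohort(
        csf=ProteinMatrix(csf_df, "CSF", group_series),
        plasma=ProteinMatrix(plasma_df, "plasma", group_series),
        covariates=covs,
        clinical=clinical,
        config=config,
    )


def inject_clinical_association(
    scores: pd.DataFrame,
    pc_axis: pd.Series,
    r_target: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-draw clinical scores so each scale correlates with a component axis.

    A Gaussian latent with correlation ``r_target`` to the (standardised)
    axis is drawn per scale, and the original score values are re-assigned by
    rank-mapping onto the latent, preserving each scale's marginal
    distribution exactly.
    """
    if not (-1.0 < r_target < 1.0):
        raise ValueError("|r_target| must be < 1")
    if len(scores) != len(pc_axis):
        raise ValueError(
            f"length mismatch: {len(scores)} scores vs {len(pc_axis)} axis values"
        )
    if not scores.index.equals(pc_axis.index):
        pc_axis = pc_axis.reindex(scores.index)
        if pc_axis.isna().any():
            raise ValueError("pc_axis not alignable with score subjects")
    rng = np.random.default_rng(seed)
    axis = pc_axis.to_numpy(dtype=float)
    axis_z = (axis - axis.mean()) / axis.std()
    out = {}
    for col in scores.columns:
        latent = r_target * axis_z + np.sqrt(1.0 - r_target**2) * rng.standard_normal(len(axis_z))
        ranks = np.argsort(np.argsort(latent))
        sorted_vals = np.sort(scores[col].to_numpy())
        out[col] = sorted_vals[ranks]
    return pd.DataFrame(out, index=scores.index)
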