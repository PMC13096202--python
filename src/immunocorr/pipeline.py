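"""End-to-end orchestration of the correlation-profiling analysis.

``run_full_analysis`` sequences every stage — per-group hub profiles, delta
profiles with Fisher-z p-values and BKY FDR flags, permutation shift tests in
both modes, complement network edges with bootstrap CIs, slope contrasts for
hub pairs, PCA with clinical-score correlations, and compartment concordance
— over either simulated or file-based input, and writes each result as a
delimited table plus a JSON run manifest.  Output is deterministic for a
fixed config and seed (no timestamps enter any emitted file).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import concordance_table, overlap_summary
from .contrast import delta_profile, flag_deltas, slope_contrast
from .correlation import hub_profile
from .fdr import bky_two_stage
from .io import read_clinical, read_covariates, read_protein_matrix, write_cohort
from .network import bootstrap_edges, edges_to_frame
from .pca import fit_pca, pc_clinical_correlation
from .shift import directional_and_absolute
from .synthetic import GROUP_FEP, GROUP_HC, Cohort, SimConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "bmi", "medication")


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    # either a simulate block ...
    simulate: SimConfig | None = None
    # ... or input file paths
    csf_path: str | None = None
    plasma_path: str | None = None
    covariates_path: str | None = None
    clinical_path: str | None = None

    hubs: tuple[str, ...] = ("C4A", "C4B", "C1QA")
    panel: tuple[str, ...] | str = "auto"  # "auto" = all non-hub CSF proteins
    covariate_cols: tuple[str, ...] = DEFAULT_COVARIATES
    method_policy: str = "spearman"
    n_perm: int = 10_000
    n_boot: int = 10_000
    q_fdr: float = 0.10
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: _coerce(k, v) for k, v in raw.items()})
        if sim is not None:
            for key in ("hub_panel_corr_hc", "hub_panel_corr_fep"):
                if key in sim:
                    sim[key] = {str(k): float(v) for k, v in sim[key].items()}
            for key in ("hub_hub_corr_hc", "hub_hub_corr_fep"):
                if key in sim:
                    sim[key] = {
                        tuple(str(p) for p in k.split("-")): float(v)
                        for k, v in sim[key].items()
                    }
            if "hub_names" in sim:
                sim["hub_names"] = tuple(sim["hub_names"])
            cfg.simulate = SimConfig(**sim)
        return cfg


def _coerce(key: str, value: Any) -> Any:
    if key in ("hubs", "covariate_cols") and isinstance(value, list):
        return tuple(value)
    if key == "panel" and isinstance(value, list):
        return tuple(value)
    return value


def _load_inputs(config: AnalysisConfig) -> Cohort:
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        return generate_cohort(sim)
    if not (config.csf_path and config.plasma_path and config.covariates_path):
        raise ValueError("config needs either a simulate block or input paths")
    csf = read_protein_matrix(config.csf_path, "CSF")
    plasma = read_protein_matrix(config.plasma_path, "plasma")
    covs = read_covariates(config.covariates_path)
    clinical = (
        read_clinical(config.clinical_path) if config.clinical_path else pd.DataFrame()
    )
    return Cohort(csf=csf, plasma=plasma, covariates=covs, clinical=clinical,
                  config=SimConfig())


def _validate(config: AnalysisConfig, cohort: Cohort) -> list[str]:
    panel = (
        [p for p in cohort.csf.values.columns if p not in config.hubs]
        if config.panel == "auto"
        else list(config.panel)
    )
    problems = []
    for h in config.hubs:
        if h not in cohort.csf.values.columns:
            problems.append(f"hub {h!r} missing from CSF matrix")
    for p in panel:
        if p not in cohort.csf.values.columns:
            problems.append(f"panel protein {p!r} missing from CSF matrix")
    for c in config.covariate_cols:
        if c not in cohort.covariates.columns:
            problems.append(f"covariate {c!r} missing from covariate table")
    if problems:
        raise ValueError("config validation failed: " + "; ".join(problems))
    return panel


def run_full_analysis(config: AnalysisConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns the path map."""
    cohort = _load_inputs(config)
    panel = _validate(config, cohort)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    covs = cohort.covariates[list(config.covariate_cols)]
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path

    # 1. hub profiles and delta profiles, per compartment
    profile_frames, delta_frames, shift_rows = [], [], []
    compartments = [("CSF", cohort.csf), ("plasma", cohort.plasma)]
    for comp_name, matrix in compartments:
        logger.info("stage: hub profiles (%s)", comp_name)
        # hubs are CSF analytes; panel proteins come from the compartment
        prot = cohort.csf.values[list(config.hubs)].join(
            matrix.values[[p for p in panel if p in matrix.values.columns]]
        )
        comp_panel = [p for p in panel if p in matrix.values.columns]
        if not comp_panel:
            continue
        for hub in config.hubs:
            profs = {}
            for group in (GROUP_HC, GROUP_FEP):
                profs[group] = hub_profile(
                    prot, covs, hub, comp_panel,
                    group_labels=cohort.csf.group, group=group,
                    method_policy=config.method_policy, compartment=comp_name,
                )
                profile_frames.append(profs[group].to_frame())
            entries = delta_profile(profs[GROUP_FEP], profs[GROUP_HC])
            ps = [e.p for e in entries if np.isfinite(e.p)]
            if ps:
                rejected = bky_two_stage(ps, q=config.q_fdr).rejected
                entries = flag_deltas(entries, rejected)
            delta_frames.append(
                pd.DataFrame([
                    {"compartment": comp_name, "hub": hub, **dataclasses.asdict(e)}
                    for e in entries
                ])
            )
            logger.info("stage: shift tests (%s, %s)", comp_name, hub)
            res_d, res_a = directional_and_absolute(
                prot, covs, cohort.csf.group, hub, comp_panel,
                n_perm=config.n_perm, seed=rng_seed,
                method_policy=config.method_policy, compartment=comp_name,
            )
            for res in (res_d, res_a):
                shift_rows.append(dataclasses.asdict(res))
    emit("hub_profiles", pd.concat(profile_frames, ignore_index=True))
    emit("delta_profiles", pd.concat(delta_frames, ignore_index=True))
    emit("shift_results", pd.DataFrame(shift_rows))

    # 2. complement network with bootstrap CIs, per group
    logger.info("stage: complement network bootstrap")
    net_frames = []
    hub_vals = cohort.csf.values[list(config.hubs)]
    for group in (GROUP_HC, GROUP_FEP):
        sub = hub_vals.loc[cohort.csf.group == group]
        edges = bootstrap_edges(sub, n_boot=config.n_boot, seed=rng_seed)
        net_frames.append(edges_to_frame(edges, group=group))
    emit("network_edges", pd.concat(net_frames, ignore_index=True))

    # 3. slope contrasts for hub pairs
    logger.info("stage: hub-pair slope contrasts")
    slope_rows = []
    is_fep = (cohort.csf.group == GROUP_FEP).to_numpy()
    for a, b in itertools.combinations(config.hubs, 2):
        x, y = cohort.csf.values[a].to_numpy(), cohort.csf.values[b].to_numpy()
        cov_arr = covs.to_numpy(dtype=float)
        sc = slope_contrast(
            x[is_fep], y[is_fep], x[~is_fep], y[~is_fep],
            covariates_fep=cov_arr[is_fep], covariates_hc=cov_arr[~is_fep],
        )
        slope_rows.append({"protein_x": a, "protein_y": b, **dataclasses.asdict(sc)})
    emit("slope_contrasts", pd.DataFrame(slope_rows))

    # 4. PCA and clinical correlations (FEP subjects, complement + panel)
    logger.info("stage: PCA / clinical correlation")
    pca_var_frames, pca_load_frames, pc_clin_frames = [], [], []
    for comp_name, matrix in compartments:
        joint = cohort.csf.values[list(config.hubs)].join(
            matrix.values[[p for p in panel if p in matrix.values.columns]]
        )
        fep_rows = joint.loc[cohort.csf.group == GROUP_FEP].dropna(how="any")
        if fep_rows.shape[0] < 6:
            logger.warning("PCA skipped for %s: too few complete subjects", comp_name)
            continue
        res = fit_pca(fep_rows, scale=True, n_components_retained=4)
        pca_var_frames.append(pd.DataFrame({
            "compartment": comp_name,
            "component": [f"PC{i+1}" for i in range(len(res.variance_explained))],
            "variance_fraction": res.variance_explained,
        }))
        load = res.loadings.reset_index(names="protein")
        load.insert(0, "compartment", comp_name)
        pca_load_frames.append(load)
        if len(cohort.clinical):
            pc_clin = pc_clinical_correlation(
                res, cohort.clinical, method_policy=config.method_policy,
                q_fdr=config.q_fdr,
            )
            pc_clin.insert(0, "compartment", comp_name)
            pc_clin_frames.append(pc_clin)
    if pca_var_frames:
        emit("pca_variance", pd.concat(pca_var_frames, ignore_index=True))
        emit("pca_loadings", pd.concat(pca_load_frames, ignore_index=True))
    if pc_clin_frames:
        emit("pc_clinical", pd.concat(pc_clin_frames, ignore_index=True))

    # 5. CSF-plasma concordance
    logger.info("stage: cross-compartment concordance")
    conc = {}
    for group in (GROUP_HC, GROUP_FEP):
        conc[group] = concordance_table(
            cohort.csf.values, cohort.plasma.values, cohort.csf.group, group,
            method_policy=config.method_policy, q_fdr=config.q_fdr,
        )
    emit("concordance", pd.concat(conc.values(), ignore_index=True))
    summary = overlap_summary(conc[GROUP_HC], conc[GROUP_FEP])

    config_dump = _jsonable(config)
    config_dump.pop("outdir", None)  # keep the manifest path-independent
    manifest = {
        "package_version": __version__,
        "seed": rng_seed,
        "config": config_dump,
        "n_subjects": {
            GROUP_HC: int((cohort.csf.group == GROUP_HC).sum()),
            GROUP_FEP: int((cohort.csf.group == GROUP_FEP).sum()),
        },
        "panel_size": len(panel),
        "concordance_overlap": summary,
        "conventions": {
            "partial_spearman": "rank-then-residualize, t approximation df=n-2-k",
            "fisher_z_variance": "1/(n-3-k) per group",
            "directional_tail": "upper (positive shift) unless flipped",
            "absolute_mode": "upper tail of mean |delta r|, null-mean centered z",
            "bootstrap_ci": "percentile 2.5/97.5",
            "fdr": "two-stage BKY linear step-up",
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def simulate_to_files(sim: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write its four CSV tables."""
    return write_cohort(generate_cohort(sim), outdir)
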