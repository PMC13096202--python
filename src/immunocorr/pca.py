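"""PCA of the combined complement + inflammation panel and its correlation
with clinical severity scores.

Proteins are centered and scaled to unit variance (so the decomposition is of
the correlation matrix), subjects with any missing value are dropped by
default (an optional mean-imputation mode exists and is recorded in the
result), and the first four components are retained for downstream analyses.
Eigenvector sign is fixed deterministically: the largest-magnitude loading of
each component is made positive.  Component scores are then correlated with
PANSS Positive/Negative/General severity scores, with two-stage BKY FDR flags
attached across the component-by-scale family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fdr as _fdr
from .correlation import correlate, decide_method


@dataclass
class PCAResult:
    variance_explained: np.ndarray  # fraction per component, all components
    loadings: pd.DataFrame          # protein x retained component
    scores: pd.DataFrame            # subject x retained component
    n_components_retained: int
    scaled: bool
    imputed: bool

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)


def fit_pca(
    proteins: pd.DataFrame,
    scale: bool = True,
    n_components_retained: int = 4,
    impute: bool = False,
) -> PCAResult:
    """PCA via SVD of the (scaled) protein matrix.

    Parameters
    ----------
    proteins : subject x protein DataFrame; missing values handled per
        ``impute`` (False: complete-case subjects; True: per-protein mean).
    scale : divide each protein by its SD after centering (correlation PCA).
    n_components_retained : components kept in loadings/scores; pass 0 or a
        value >= min(n-1, p) to retain all.
    """
    df = proteins.astype(float)
    if impute:
        df = df.fillna(df.mean())
    else:
        df = df.dropna(axis=0, how="any")
    x = df.to_numpy()
    n, p = x.shape
    constant = [str(c) for c, s in zip(df.columns, x.std(axis=0)) if s == 0]
    if constant:
        raise ValueError(f"constant protein(s) across subjects: {constant}")
    max_rank = min(n - 1, p)
    if n_components_retained <= 0 or n_components_retained > max_rank:
        n_components_retained = max_rank
    if n < n_components_retained + 2:
        raise ValueError(
            f"need >= {n_components_retained + 2} complete subjects, have {n}"
        )

    x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()

    # deterministic sign: largest-|loading| entry of each component positive
    v = vt.T
    for j in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, j])))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]

    k = n_components_retained
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(v[:, :k], index=df.columns, columns=comp_names)
    scores = pd.DataFrame(u[:, :k] * s[:k], index=df.index, columns=comp_names)
    return PCAResult(
        variance_explained=var_frac,
        loadings=loadings,
        scores=scores,
        n_components_retained=k,
        scaled=scale,
        imputed=impute,
    )


def top_loadings(result: PCAResult, component: str | int, k: int) -> list[str]:
    """Top-k proteins of a component by |loading|, ties broken alphabetically."""
    if isinstance(component, int):
        component = f"PC{component}"
    if component not in result.loadings.columns:
        raise KeyError(f"component {component} not retained")
    if k > result.loadings.shape[0]:
        raise ValueError(f"k={k} exceeds panel size {result.loadings.shape[0]}")
    col = result.loadings[component]
    order = sorted(col.index, key=lambda name: (-abs(col[name]), str(name)))
    return [str(n) for n in order[:k]]


def pc_clinical_correlation(
    result: PCAResult,
    clinical: pd.DataFrame,
    method_policy: str = "spearman",
    q_fdr: float = 0.10,
) -> pd.DataFrame:
    """Correlate retained component scores with clinical severity scales.

    ``clinical`` is a subject x scale DataFrame (e.g. PANSS Positive /
    Negative / General); overlap with PCA scores must cover >= 5 subjects.
    Returns one row per (component, scale) with r, p, n and a BKY FDR flag
    across the whole family.
    """
    shared = result.scores.index.intersection(clinical.index)
    if len(shared) < 5:
        raise ValueError(
            f"only {len(shared)} subjects overlap between PCA scores and "
            "clinical scores; need >= 5"
        )
    rows = []
    for comp in result.component_names:
        for scale_name in clinical.columns:
            x = result.scores.loc[shared, comp]
            y = clinical.loc[shared, scale_name]
            if method_policy == "auto":
                method = decide_method(x, y).chosen
            else:
                method = method_policy  # type: ignore[assignment]
            res = correlate(x, y, method=method)
            rows.append(
                {
                    "component": comp,
                    "scale": str(scale_name),
                    "r": res.r,
                    "p": res.p,
                    "n": res.n_eff,
                    "method": res.method,
                }
            )
    table = pd.DataFrame(rows)
    usable = table["p"].notna()
    flags = np.zeros(len(table), dtype=bool)
    if usable.any():
        outcome = _fdr.bky_two_stage(table.loc[usable, "p"].to_numpy(), q=q_fdr)
        flags[np.flatnonzero(usable.to_numpy())] = outcome.rejected
    table["fdr_significant"] = flags
    return table
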