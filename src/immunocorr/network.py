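"""Zero-order Spearman correlation network with bootstrap edge stability.

The complement network (e.g. C4A, C4B, C1QA in one compartment) is estimated
as all pairwise Spearman correlations without regularization or covariate
adjustment (zero-order), with pairwise deletion of missing values.  Edge
stability is assessed by nonparametric bootstrapping: subjects are resampled
with replacement within the group and the whole network recomputed per
resample; 2.5/97.5 percentile intervals per edge are reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import MIN_PAIRS, correlate

logger = logging.getLogger(__name__)

MIN_BOOT = 200
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class EdgeEstimate:
    node_a: str
    node_b: str
    weight: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0
    n_eff: int = 0
    usable: bool = True


def estimate_network(
    proteins: pd.DataFrame,
    nodes: list[str] | None = None,
) -> list[EdgeEstimate]:
    """All pairwise zero-order Spearman edges over the node set.

    Edges with fewer than 4 complete pairs are flagged unusable.
    """
    if nodes is None:
        nodes = [str(c) for c in proteins.columns]
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes")
    absent = [n for n in nodes if n not in proteins.columns]
    if absent:
        raise KeyError(f"node(s) absent from data: {absent}")
    edges = []
    for a, b in itertools.combinations(nodes, 2):
        res = correlate(proteins[a], proteins[b], method="spearman")
        edges.append(
            EdgeEstimate(
                node_a=a, node_b=b, weight=res.r,
                n_eff=res.n_eff, usable=res.usable,
            )
        )
    return edges


def bootstrap_edges(
    proteins: pd.DataFrame,
    nodes: list[str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> list[EdgeEstimate]:
    """Percentile bootstrap confidence intervals on network edge weights.

    Subjects are resampled with replacement; resamples in which any node is
    constant (ties everywhere, Spearman undefined) are redrawn with a logged
    counter.  Deterministic under ``seed``.
    """
    if n_boot < MIN_BOOT:
        raise ValueError(f"n_boot must be >= {MIN_BOOT}, got {n_boot}")
    if nodes is None:
        nodes = [str(c) for c in proteins.columns]
    point = estimate_network(proteins, nodes)
    values = proteins[nodes].to_numpy(dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    boot = np.empty((n_boot, len(pairs)))
    redraws = 0
    for b in range(n_boot):
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, size=n)
            sample = values[idx]
            finite_ptp = [
                np.ptp(col[np.isfinite(col)]) if np.isfinite(col).sum() else 0.0
                for col in sample.T
            ]
            if all(p > 0 for p in finite_ptp):
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        for e, (i, j) in enumerate(pairs):
            boot[b, e] = correlate(sample[:, i], sample[:, j], "spearman").r
    if redraws:
        logger.info("bootstrap: %d degenerate resamples redrawn", redraws)

    out = []
    for e, edge in enumerate(point):
        col = boot[:, e]
        col = col[np.isfinite(col)]
        if col.size == 0:
            out.append(edge)
            continue
        lo, hi = np.percentile(col, ci)
        out.append(
            EdgeEstimate(
                node_a=edge.node_a, node_b=edge.node_b, weight=edge.weight,
                ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
                n_eff=edge.n_eff, usable=edge.usable,
            )
        )
    return out


def edges_to_frame(edges: list[EdgeEstimate], group: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": group,
            "node_a": [e.node_a for e in edges],
            "node_b": [e.node_b for e in edges],
            "weight": [e.weight for e in edges],
            "ci_low": [e.ci_low for e in edges],
            "ci_high": [e.ci_high for e in edges],
            "n_boot": [e.n_boot for e in edges],
            "n_eff": [e.n_eff for e in edges],
            "usable": [e.usable for e in edges],
        }
    )
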