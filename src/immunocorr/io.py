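"""Delimited-text I/O for protein matrices, covariates and clinical scores.

All files are UTF-8 CSV with a header row, '.' decimal separator and the
empty string for missing values.  A protein matrix file has columns
``subject_id``, ``group``, then one numeric column per protein.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, ProteinMatrix

logger = logging.getLogger(__name__)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.insert(0, "group", matrix.group)
    df.index.name = "subject_id"
    df.to_csv(path, float_format="%.10g")


def read_protein_matrix(path: str | Path, compartment: str) -> ProteinMatrix:
    """Read a subject x protein CSV into a typed matrix.

    Duplicate subject ids and non-numeric cells are rejected with
    coordinates; all-empty protein columns are retained as all-missing with
    a logged warning.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "subject_id" not in raw.columns or "group" not in raw.columns:
        raise ValueError(f"{path}: expected 'subject_id' and 'group' columns")
    ids = raw["subject_id"]
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"{path}: duplicate subject_id(s): {dups}")
    prot_cols = [c for c in raw.columns if c not in ("subject_id", "group")]
    values = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    for col in prot_cols:
        cells = raw[col].str.strip()
        empty = cells == ""
        parsed = pd.to_numeric(cells.where(~empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row + 2} (subject "
                f"{ids.iloc[row]!r}), column {col!r}: {cells.iloc[row]!r}"
            )
        if empty.all():
            logger.warning("%s: column %r is entirely missing", path, col)
        values[col] = parsed.to_numpy(dtype=float)
    group = pd.Series(raw["group"].to_numpy(), index=values.index, name="group")
    return ProteinMatrix(values=values, compartment=compartment, group=group)


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    out = covariates.copy()
    out.index.name = "subject_id"
    out.to_csv(path, float_format="%.10g")


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate subject_id(s)")
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out.index.name = "subject_id"
    out.to_csv(path)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate subject_id(s)")
    return df


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write all four cohort tables as CSV; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csf": outdir / "csf_proteins.csv",
        "plasma": outdir / "plasma_proteins.csv",
        "covariates": outdir / "covariates.csv",
        "clinical": outdir / "clinical_scores.csv",
    }
    write_protein_matrix(cohort.csf, paths["csf"])
    write_protein_matrix(cohort.plasma, paths["plasma"])
    write_covariates(cohort.covariates, paths["covariates"])
    write_clinical(cohort.clinical, paths["clinical"])
    return paths
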