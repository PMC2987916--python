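"""Delimited-text readers/writers for cohorts, correlation matrices and edge lists.

All files are UTF-8 CSV (TSV when the path ends in ``.tsv``). Every file
written by covnet starts with a ``#`` comment line recording the package
version and the parameters that produced it; readers skip and, where useful,
parse that line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import RegionAtlas, aal_region_table
from .cohort import COVARIATE_COLUMNS, Cohort
from .exceptions import CohortFormatError, ContractError

_ID_COLUMN = "subject_id"


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() == ".tsv" else ","


def _comment_line(**params) -> str:
    fields = " ".join(f"{k}={v}" for k, v in params.items() if v is not None)
    return f"# covnet {__version__}" + (f" | {fields}" if fields else "")


def _parse_comment(path: Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    meta: dict[str, str] = {}
    if first.startswith("#") and "|" in first:
        for token in first.split("|", 1)[1].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def read_cohort(path, group_label: str, atlas: RegionAtlas | None = None) -> Cohort:
    """Read a cohort table.

    The file must have a header row with ``subject_id``, ``age``, ``sex``,
    ``total_gm_volume`` and one column per atlas region named by its
    abbreviation; region columns may appear in any order and are reordered
    into atlas order.
    """
    path = Path(path)
    atlas = atlas or aal_region_table()
    df = pd.read_csv(path, sep=_delimiter(path), comment="#", dtype={_ID_COLUMN: str},
                     float_precision="round_trip")

    required = [_ID_COLUMN, *COVARIATE_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r} in {path.name}")
    counts = pd.Series(df.columns).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise CohortFormatError(f"duplicate column(s) {dups} in {path.name}")
    missing = [a for a in atlas.abbreviations if a not in df.columns]
    if missing:
        raise CohortFormatError(f"missing region column(s) {missing} in {path.name}")

    numeric_cols = list(COVARIATE_COLUMNS) + atlas.abbreviations
    numeric = df[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[numeric_cols].notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        rows = np.nonzero(numeric.isna().any(axis=1).to_numpy())[0]
        raise CohortFormatError(
            f"non-numeric or missing cell(s) at data row(s) {rows.tolist()[:5]} in {path.name}"
        )

    volumes = numeric[atlas.abbreviations].copy()
    volumes.index = df[_ID_COLUMN].tolist()
    covariates = numeric[list(COVARIATE_COLUMNS)].copy()
    covariates.index = df[_ID_COLUMN].tolist()
    return Cohort(group_label=group_label, volumes=volumes, covariates=covariates, atlas=atlas)


def write_cohort(cohort: Cohort, path, seed: int | None = None) -> None:
    """Write a cohort to delimited text (inverse of :func:`read_cohort`)."""
    path = Path(path)
    out = cohort.covariates.loc[:, list(COVARIATE_COLUMNS)].join(cohort.volumes)
    out.insert(0, _ID_COLUMN, [str(i) for i in cohort.volumes.index])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment_line(kind="cohort", group=cohort.group_label, seed=seed,
                               n_subjects=cohort.n_subjects) + "\n")
        out.to_csv(fh, sep=_delimiter(path), index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, path, atlas: RegionAtlas | None = None,
                 group_label: str | None = None, n_subjects: int | None = None,
                 seed: int | None = None) -> None:
    """Write a symmetric region × region matrix as labeled dense CSV."""
    path = Path(path)
    atlas = atlas or aal_region_table()
    matrix = np.asarray(matrix, dtype=float)
    n = atlas.n_regions
    if matrix.shape != (n, n):
        raise ContractError(f"matrix shape {matrix.shape} does not match atlas size {n}")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ContractError("matrix must be symmetric")
    labels = atlas.abbreviations
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment_line(kind="matrix", group=group_label,
                               n_subjects=n_subjects, seed=seed) + "\n")
        df.to_csv(fh, sep=_delimiter(path), index_label="region")


def read_matrix(path, atlas: RegionAtlas | None = None):
    """Read a labeled matrix written by :func:`write_matrix`.

    Returns ``(matrix, metadata)`` where metadata carries any ``group`` /
    ``n_subjects`` recorded in the file's comment line.
    """
    path = Path(path)
    atlas = atlas or aal_region_table()
    df = pd.read_csv(path, sep=_delimiter(path), comment="#", index_col=0,
                     float_precision="round_trip")
    labels = atlas.abbreviations
    if list(df.columns) != labels or list(df.index) != labels:
        raise CohortFormatError(f"matrix labels in {path.name} do not match the atlas")
    meta = _parse_comment(path)
    if "n_subjects" in meta:
        meta["n_subjects"] = int(meta["n_subjects"])
    return df.to_numpy(dtype=float), meta


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_edge_list(edges, path, atlas: RegionAtlas | None = None,
                    value_name: str = "value", seed: int | None = None,
                    extra_columns: pd.DataFrame | None = None) -> None:
    """Write ``(i, j, value)`` edges (0-based region indices, i < j) as CSV.

    ``edges`` is an iterable of ``(i, j, value)`` triples; indices are
    converted to atlas abbreviations. ``extra_columns`` (aligned row-wise)
    may append further per-edge columns such as p-values or directions.
    """
    path = Path(path)
    atlas = atlas or aal_region_table()
    labels = atlas.abbreviations
    rows = []
    for i, j, value in edges:
        if not 0 <= i < j < atlas.n_regions:
            raise ContractError(f"edge ({i}, {j}) is not an i<j pair of region indices")
        rows.append((labels[i], labels[j], value))
    df = pd.DataFrame(rows, columns=["region_i", "region_j", value_name])
    if extra_columns is not None:
        df = pd.concat([df, extra_columns.reset_index(drop=True)], axis=1)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_comment_line(kind="edge_list", n_edges=len(df), seed=seed) + "\n")
        df.to_csv(fh, sep=_delimiter(path), index=False)


def read_edge_list(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter(path), comment="#")
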