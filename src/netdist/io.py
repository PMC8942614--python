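"""File input/output: connectivity matrices, covariate tables, distances.

Connectivity matrices are dense square numeric CSVs (no header by default);
the filename stem is the subject id. Covariate tables are CSVs whose first
column is the subject id. Subjects are ordered lexicographically by id
everywhere, and the pair index is derived from that single ordering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import CovariateTable
from .features import ConnectionMatrix
from .pairs import PairIndex, PairwiseVector

__all__ = [
    "read_connectivity_dir",
    "read_connectivity_csv",
    "write_connectivity_csv",
    "read_covariates",
    "write_distances",
    "read_distances",
]


def read_connectivity_csv(path, subject_id: str | None = None, header: bool = False) -> ConnectionMatrix:
    """One subject's connection matrix from a dense square CSV.

    With ``header=True`` the first row and first column are treated as node
    labels; otherwise the file is purely numeric.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    try:
        if header:
            df = pd.read_csv(path, index_col=0)
            W = df.to_numpy(dtype=float)
            node_ids = tuple(df.columns)
        else:
            W = np.loadtxt(path, delimiter=",", ndmin=2)
            node_ids = None
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse numeric matrix ({exc})") from exc
    try:
        return ConnectionMatrix(W, subject_id=subject_id, node_ids=node_ids)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_connectivity_csv(C: ConnectionMatrix, path) -> None:
    np.savetxt(path, C.weights, delimiter=",", fmt="%.17g")


def read_connectivity_dir(path, header: bool = False) -> list:
    """All per-subject matrices in a directory, sorted by subject id.

    Every file must hold a valid matrix and all matrices must share the same
    dimension; offending files are reported together.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv"), key=lambda p: p.stem)
    if not files:
        raise ValueError(f"no .csv connectivity matrices found in {path}")
    matrices = []
    errors = []
    for f in files:
        try:
            matrices.append(read_connectivity_csv(f, header=header))
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid connectivity files:\n" + "\n".join(errors))
    sizes = {m.n_nodes for m in matrices}
    if len(sizes) > 1:
        detail = ", ".join(f"{m.subject_id}: {m.n_nodes}" for m in matrices)
        raise ValueError(f"matrices have mixed dimensions ({detail})")
    return matrices


def read_covariates(
    path,
    continuous=(),
    categorical=(),
    coi: str = None,
    subject_ids=None,
) -> CovariateTable:
    """Covariate table from CSV (first column: subject id).

    Column roles are declared by the caller; when ``subject_ids`` (e.g. from
    the connectivity directory) is given, the table must match it exactly.
    Rows are sorted lexicographically by subject id.
    """
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    dupes = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate subject ids in {path}: {dupes}")
    df = df.set_index(id_col).sort_index()
    for col in continuous:
        if col not in df.columns:
            raise ValueError(f"continuous column {col!r} not found in {path}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise ValueError(
                f"non-numeric values in continuous column {col!r} for subjects {bad}"
            )
        df[col] = coerced
    if subject_ids is not None:
        want = set(map(str, subject_ids))
        have = set(df.index)
        if want != have:
            missing = sorted(want - have)
            extra = sorted(have - want)
            raise ValueError(
                f"covariate/connectivity subject mismatch; missing from table: "
                f"{missing}; unmatched in table: {extra}"
            )
    return CovariateTable(
        df, continuous=tuple(continuous), categorical=tuple(categorical), coi=coi
    )


def write_distances(dist: PairwiseVector, path) -> None:
    """Condensed distances as CSV with columns subject_i, subject_j, value, metric."""
    dist.to_frame().to_csv(path, index=False)


def read_distances(path) -> PairwiseVector:
    """Read a condensed distance CSV written by :func:`write_distances`.

    Subject order (hence pair order) is re-derived lexicographically; the
    file must contain every pair exactly once.
    """
    df = pd.read_csv(path, dtype={"subject_i": str, "subject_j": str})
    ids = sorted(set(df["subject_i"]) | set(df["subject_j"]))
    index = PairIndex.from_subject_ids(ids)
    pos = {s: k for k, s in enumerate(ids)}
    n = index.n_pairs
    if len(df) != n:
        raise ValueError(
            f"{path}: expected {n} pairs for {len(ids)} subjects, found {len(df)}"
        )
    values = np.full(n, np.nan)
    for si, sj, v in zip(df["subject_i"], df["subject_j"], df["value"]):
        values[index.row_of(pos[si], pos[sj])] = v
    if np.isnan(values).any():
        raise ValueError(f"{path}: duplicate or missing pairs")
    metric = str(df["metric"].iloc[0]) if "metric" in df else ""
    transform = "log" if metric == "log_ks" else "none"
    return PairwiseVector(values, index, metric_name=metric, transform=transform)
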