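"""Pairwise regression designs from a subject covariate table.

The regression relates a pairwise network distance to pairwise covariate
differences: a continuous covariate enters as the absolute difference
``|x_i - x_j|``; a categorical (including binary, and multi-level treated as
a whole) covariate enters as the indicator ``1{x_i != x_j}``. The covariate
of interest (coi) is always the last column, after any confounders.

An optional individual-level-effects (ILE) block adds one indicator column
per participant; the row for pair ``(i, j)`` has ones exactly at columns
``i`` and ``j``. The ILE columns sum to twice the intercept, so the
intercept is dropped whenever the block is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairs import PairIndex

__all__ = ["CovariateTable", "DesignMatrix", "build_design", "ile_block"]


@dataclass
class CovariateTable:
    """Typed view of a subject covariate table.

    ``data`` is indexed by subject id (unique, sorted order is the caller's
    canonical subject order); ``continuous`` and ``categorical`` name the
    modeled columns; ``coi`` names the covariate of interest.
    """

    data: pd.DataFrame
    continuous: tuple
    categorical: tuple
    coi: str

    def __post_init__(self):
        self.continuous = tuple(self.continuous)
        self.categorical = tuple(self.categorical)
        modeled = self.continuous + self.categorical
        missing = [c for c in modeled if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        if self.coi not in modeled:
            raise ValueError(
                f"covariate of interest {self.coi!r} is not a modeled column"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        for col in modeled:
            s = self.data[col]
            if s.isna().any():
                bad = self.data.index[s.isna()].tolist()
                raise ValueError(f"missing values in column {col!r} for subjects {bad}")
            if col in self.continuous and not np.issubdtype(
                np.asarray(s).dtype, np.number
            ):
                raise ValueError(f"continuous column {col!r} is not numeric")

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.data.index)

    @property
    def confounders(self) -> tuple:
        return tuple(
            c for c in self.continuous + self.categorical if c != self.coi
        )


@dataclass
class DesignMatrix:
    """n-pairs x p design aligned to a :class:`PairIndex`.

    ``columns`` names every column; ILE columns are named ``"ile:<id>"``.
    """

    values: np.ndarray
    columns: tuple
    index: PairIndex
    has_intercept: bool = False
    n_ile: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(self.columns)
        if self.values.shape != (self.index.n_pairs, len(self.columns)):
            raise ValueError(
                f"design shape {self.values.shape} does not match "
                f"({self.index.n_pairs}, {len(self.columns)})"
            )

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def drop(self, name: str) -> "DesignMatrix":
        """A copy without the named (non-ILE) column."""
        k = self.columns.index(name)
        return DesignMatrix(
            np.delete(self.values, k, axis=1),
            tuple(c for c in self.columns if c != name),
            self.index,
            has_intercept=self.has_intercept and name != "intercept",
            n_ile=self.n_ile,
        )


def ile_block(index: PairIndex) -> np.ndarray:
    """Individual-level-effects indicator block.

    Returns the ``n_pairs x n_p`` binary matrix whose row for pair ``(i, j)``
    has ones exactly at columns ``i`` and ``j``. Every row sums to 2 and every
    column sums to ``n_p - 1`` (each subject belongs to that many pairs).
    """
    if index.n_p < 3:
        raise ValueError(
            "individual-level effects need at least 3 participants to be identifiable"
        )
    I, J = index.members
    n = index.n_pairs
    B = np.zeros((n, index.n_p))
    rows = np.arange(n)
    B[rows, I] = 1.0
    B[rows, J] = 1.0
    return B


def _pairwise_column(values: np.ndarray, kind: str, I, J) -> np.ndarray:
    if kind == "continuous":
        v = np.asarray(values, dtype=float)
        return np.abs(v[I] - v[J])
    # categorical (binary or multi-level): different-membership indicator
    v = np.asarray(values)
    return (v[I] != v[J]).astype(float)


def build_design(
    cov: CovariateTable,
    index: PairIndex | None = None,
    *,
    include_intercept: bool = True,
    include_ile: bool = False,
) -> DesignMatrix:
    """Assemble the pairwise design matrix from a covariate table.

    Column order is ``[intercept?, ILE block?, confounders..., coi]``; the
    covariate of interest is always last. Continuous covariates become
    absolute pairwise differences, categorical ones become ``1{!=}``
    indicators (multi-level categories collapse to a single indicator).
    With the ILE block present the intercept is linearly dependent (the ILE
    columns sum to twice the intercept) and is dropped.

    Raises on a constant pairwise column: the covariate would be untestable.
    """
    ids = cov.subject_ids
    if index is None:
        index = PairIndex.from_subject_ids(ids)
    else:
        if index.n_p != len(ids):
            raise ValueError("pair index and covariate table disagree on n_p")
        if index.subject_ids is not None and tuple(index.subject_ids) != ids:
            raise ValueError("pair index subject ids do not match covariate table")
    I, J = index.members

    names: list = []
    cols: list = []
    n_ile = 0
    if include_ile:
        B = ile_block(index)
        names.extend(f"ile:{s}" for s in ids)
        cols.append(B)
        n_ile = index.n_p
        include_intercept = False  # sum of ILE columns = 2 * intercept
    elif include_intercept:
        names.append("intercept")
        cols.append(np.ones((index.n_pairs, 1)))

    order = list(cov.confounders) + [cov.coi]
    for name in order:
        kind = "continuous" if name in cov.continuous else "categorical"
        col = _pairwise_column(cov.data[name].to_numpy(), kind, I, J)
        if np.all(col == col[0]) and index.n_pairs > 1 and col[0] == 0.0:
            raise ValueError(
                f"covariate {name!r} is identical for all subjects "
                "(constant zero pairwise column)"
            )
        names.append(name)
        cols.append(col.reshape(-1, 1))

    X = np.hstack(cols)
    return DesignMatrix(
        X,
        tuple(names),
        index,
        has_intercept=include_intercept and not include_ile,
        n_ile=n_ile,
    )
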