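"""Indexing of unordered subject pairs.

Every downstream object — distance vectors, design matrices, residual
covariances — lives on the :math:`n = \\binom{n_p}{2}` unordered pairs of
participants. ``PairIndex`` fixes a single canonical ordering (lexicographic
``(i, j)`` with ``i < j``, 0-based) so that distances and design rows can
never silently misalign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PairIndex", "PairwiseVector", "condensed_index"]


def condensed_index(i, j, n_p: int):
    """Row number of pair ``(i, j)`` in the condensed ordering.

    Accepts scalars or arrays; ``i`` and ``j`` need not be ordered.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    return lo * (2 * n_p - lo - 1) // 2 + (hi - lo - 1)


@dataclass(frozen=True)
class PairIndex:
    """Canonical ordering of the C(n_p, 2) unordered participant pairs."""

    n_p: int
    subject_ids: tuple = None

    def __post_init__(self):
        if self.n_p < 2:
            raise ValueError("PairIndex requires at least 2 participants")
        if self.subject_ids is not None:
            ids = tuple(self.subject_ids)
            if len(ids) != self.n_p:
                raise ValueError(
                    f"{len(ids)} subject ids for n_p={self.n_p} participants"
                )
            object.__setattr__(self, "subject_ids", ids)

    @property
    def n_pairs(self) -> int:
        return self.n_p * (self.n_p - 1) // 2

    def __len__(self) -> int:
        return self.n_pairs

    @property
    def members(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(I, J)`` with the two members of each pair, I < J."""
        return np.triu_indices(self.n_p, k=1)

    def pairs(self):
        """Iterate over ``(i, j)`` tuples in condensed order."""
        I, J = self.members
        return list(zip(I.tolist(), J.tolist()))

    def row_of(self, i: int, j: int) -> int:
        if i == j or not (0 <= i < self.n_p and 0 <= j < self.n_p):
            raise ValueError(f"invalid pair ({i}, {j}) for n_p={self.n_p}")
        return int(condensed_index(i, j, self.n_p))

    @classmethod
    def from_subject_ids(cls, subject_ids: Sequence) -> "PairIndex":
        return cls(n_p=len(list(subject_ids)), subject_ids=tuple(subject_ids))


@dataclass
class PairwiseVector:
    """A length-C(n_p,2) vector aligned to a :class:`PairIndex`.

    ``transform`` records whether the stored values are on a transformed
    scale ("log") or raw ("none"); pre-transform distances are non-negative.
    """

    values: np.ndarray
    index: PairIndex
    metric_name: str = ""
    transform: str = "none"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.index.n_pairs:
            raise ValueError(
                f"values length {self.values.shape} does not match "
                f"C({self.index.n_p},2)={self.index.n_pairs}"
            )
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "none" and np.any(self.values < -1e-12):
            raise ValueError("untransformed distances must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self):
        """Long-format DataFrame with columns subject_i, subject_j, value, metric."""
        import pandas as pd

        I, J = self.index.members
        ids = self.index.subject_ids
        si = [ids[i] for i in I] if ids is not None else I
        sj = [ids[j] for j in J] if ids is not None else J
        return pd.DataFrame(
            {
                "subject_i": si,
                "subject_j": sj,
                "value": self.values,
                "metric": self.metric_name,
            }
        )
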