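"""Nodal features of weighted brain networks.

A subject's functional connectome is a symmetric weighted adjacency matrix
with entries in [0, 1] and a zero diagonal. The features consumed by the
distance metrics are per-node summaries of that matrix:

* the **weighted degree vector** — row sums of the connection matrix;
* the **key-node (hub) vector** — a binary indicator of the nodes in the
  top fraction (conventionally 20%) of the degree ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConnectionMatrix",
    "DegreeVector",
    "KeyNodeVector",
    "degree_vector",
    "key_nodes",
]

SYMMETRY_TOL = 1e-8


@dataclass
class ConnectionMatrix:
    """Symmetric weighted adjacency matrix for one subject.

    Entries lie in [0, 1] (0 = no connection, 1 = strongest), the diagonal
    is zero, and the matrix is symmetric within an absolute tolerance of
    1e-8 (in which case it is symmetrized as ``(C + C.T) / 2``).
    """

    weights: np.ndarray
    subject_id: str = ""
    node_ids: Sequence = None

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"connection matrix must be square, got {W.shape}")
        if W.shape[0] < 2:
            raise ValueError("connection matrix needs at least 2 nodes")
        asym = np.abs(W - W.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"matrix is asymmetric (max |C - C.T| = {asym:.3g} "
                f"> tol {SYMMETRY_TOL:g})"
                + (f" for subject {self.subject_id}" if self.subject_id else "")
            )
        W = (W + W.T) / 2.0
        if np.any(np.diag(W) != 0):
            raise ValueError("connection matrix must have a zero diagonal")
        if W.min() < 0 or W.max() > 1:
            raise ValueError(
                f"entries must lie in [0, 1]; found range "
                f"[{W.min():.3g}, {W.max():.3g}]"
            )
        self.weights = W
        if self.node_ids is None:
            self.node_ids = tuple(range(W.shape[0]))
        else:
            self.node_ids = tuple(self.node_ids)
            if len(self.node_ids) != W.shape[0]:
                raise ValueError("node_ids length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class DegreeVector:
    """Weighted nodal degree (sum of incident edge weights) per node."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("degree vector must be a non-empty 1-D array")
        if np.any(v < 0):
            raise ValueError("degrees must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class KeyNodeVector:
    """Binary indicator of key (hub) nodes, plus the rule that produced it."""

    values: np.ndarray
    subject_id: str = ""
    selection_rule: tuple = ("degree-top-fraction", None)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("key-node vector must be a non-empty 1-D array")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("key-node vector entries must be 0 or 1")
        self.values = v.astype(np.int8)

    def __len__(self) -> int:
        return len(self.values)


def degree_vector(C: ConnectionMatrix) -> DegreeVector:
    """Weighted degree of every node: the row sums of the connection matrix.

    Because the matrix is symmetric with a zero diagonal, row sums equal
    column sums, and the degrees sum to twice the total edge weight
    (= the sum of all matrix entries).
    """
    if not isinstance(C, ConnectionMatrix):
        C = ConnectionMatrix(np.asarray(C))
    return DegreeVector(C.weights.sum(axis=1), subject_id=C.subject_id)


def key_nodes(d: DegreeVector, fraction: float = 0.2) -> KeyNodeVector:
    """Binary hub indicator: the top ``fraction`` of nodes ranked by degree.

    Exactly ``k = round(fraction * n_n)`` entries are set to 1 (round half
    to even). Nodes are ranked by degree descending; ties at the boundary
    are broken by ascending node index, so the output is deterministic.
    Equivalent to binarizing the degree vector at its (1 - fraction)
    quantile under that tie rule.
    """
    if isinstance(d, DegreeVector):
        values, sid = d.values, d.subject_id
    else:
        values, sid = np.asarray(d, dtype=float), ""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(values)
    k = int(np.round(fraction * n))
    # sort by degree descending, node index ascending within ties
    order = np.lexsort((np.arange(n), -values))
    out = np.zeros(n, dtype=np.int8)
    out[order[:k]] = 1
    if k == 0:
        warnings.warn(
            f"fraction {fraction} of {n} nodes rounds to an empty key set",
            stacklevel=2,
        )
    return KeyNodeVector(
        out, subject_id=sid, selection_rule=("degree-top-fraction", fraction)
    )
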