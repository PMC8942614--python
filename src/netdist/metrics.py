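"""Similarity/dissimilarity metrics between subjects' nodal features.

Three families of metric, each sensitive to a different kind of network
difference:

* **KS statistic** between empirical degree distributions — sensitive to
  differences in degree *distribution*, blind to node location. Emitted on
  the natural-log scale by default (the only metric here that benefits from
  the transform).
* **Jaccard distance / index** between binary key-node sets — sensitive to
  the spatial location of hubs.
* **Minkowski (p=2: Euclidean) and Canberra distances** between degree
  vectors — sensitive to node-wise degree differences.

``pairwise_distances`` applies a metric to every unordered pair of subjects
and returns a condensed :class:`~netdist.pairs.PairwiseVector`.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from ._ks import ks_two_sample, pairwise_ks
from .features import DegreeVector, KeyNodeVector
from .pairs import PairIndex, PairwiseVector

__all__ = [
    "ks_statistic",
    "log_ks",
    "jaccard_distance",
    "jaccard_index",
    "minkowski_distance",
    "euclidean_distance",
    "canberra_distance",
    "pairwise_distances",
    "condensed_values",
    "KS_LOG_FLOOR",
]

logger = logging.getLogger(__name__)

# identical empirical distributions give KS = 0; the floor keeps log(KS) finite
KS_LOG_FLOOR = 1e-12


def _values(x) -> np.ndarray:
    if isinstance(x, (DegreeVector, KeyNodeVector)):
        return x.values
    return np.asarray(x)


def ks_statistic(d_i, d_j) -> float:
    """Kolmogorov-Smirnov statistic between two empirical degree distributions.

    ``sup_x |F_i(x) - F_j(x)|`` where ``F`` is the empirical CDF of the
    entries of each degree vector; lies in [0, 1].
    """
    x, y = _values(d_i).astype(float), _values(d_j).astype(float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS statistic requires non-empty degree vectors")
    return ks_two_sample(x, y)


def log_ks(ks: float, floor: float = KS_LOG_FLOOR) -> float:
    """Natural log of the KS statistic, floored to stay finite at KS = 0."""
    if ks < 0:
        raise ValueError("KS statistic cannot be negative")
    if ks < floor:
        logger.info("KS statistic %g below floor %g before log", ks, floor)
    return float(np.log(max(ks, floor)))


def _binary_pair(b_i, b_j) -> tuple[np.ndarray, np.ndarray]:
    x, y = _values(b_i), _values(b_j)
    if x.shape != y.shape:
        raise ValueError("key-node vectors must have equal length")
    for v in (x, y):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("key-node vectors must be binary")
    return x.astype(bool), y.astype(bool)


def jaccard_distance(b_i, b_j) -> float:
    """Proportion of key nodes (in either set) that do not share key status.

    ``(M01 + M10) / (M11 + M01 + M10)`` where ``M11`` counts nodes key in
    both, ``M01``/``M10`` key in exactly one. 0 = perfect overlap, 1 = none.
    Both sets empty is a 0/0 case, defined as distance 0 (with a warning);
    it cannot occur under the top-fraction hub rule.
    """
    x, y = _binary_pair(b_i, b_j)
    m11 = np.sum(x & y)
    m_mismatch = np.sum(x ^ y)
    denom = m11 + m_mismatch
    if denom == 0:
        warnings.warn(
            "both key-node sets are empty; Jaccard distance defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(m_mismatch / denom)


def jaccard_index(b_i, b_j) -> float:
    """Proportion of key nodes shared: ``1 - jaccard_distance``."""
    return 1.0 - jaccard_distance(b_i, b_j)


def minkowski_distance(d_i, d_j, p: float = 2.0) -> float:
    """Minkowski distance ``(sum_k |d_i[k] - d_j[k]|^p)^(1/p)``, p >= 1."""
    if p < 1:
        raise ValueError(f"Minkowski order must satisfy p >= 1, got {p}")
    x, y = _values(d_i).astype(float), _values(d_j).astype(float)
    if x.shape != y.shape:
        raise ValueError("degree vectors must have equal length")
    return float(np.sum(np.abs(x - y) ** p) ** (1.0 / p))


def euclidean_distance(d_i, d_j) -> float:
    """Euclidean distance between degree vectors (Minkowski with p = 2)."""
    return minkowski_distance(d_i, d_j, p=2.0)


def canberra_distance(d_i, d_j) -> float:
    """Canberra distance ``sum_k |x_k - y_k| / (|x_k| + |y_k|)``.

    Terms with ``x_k = y_k = 0`` contribute 0 (the standard convention).
    """
    x, y = _values(d_i).astype(float), _values(d_j).astype(float)
    if x.shape != y.shape:
        raise ValueError("degree vectors must have equal length")
    num = np.abs(x - y)
    den = np.abs(x) + np.abs(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


_WEIGHTED_METRICS = ("ks", "euclidean", "minkowski", "canberra")
_BINARY_METRICS = ("jaccard", "jaccard_index")


def _feature_matrix(features: Sequence, binary: bool) -> np.ndarray:
    if len(features) < 2:
        raise ValueError("pairwise distances need at least 2 subjects")
    kinds = {type(f) for f in features if isinstance(f, (DegreeVector, KeyNodeVector))}
    if binary:
        if any(isinstance(f, DegreeVector) for f in features):
            raise ValueError("binary metrics require key-node vectors, not degrees")
    else:
        if any(isinstance(f, KeyNodeVector) for f in features):
            raise ValueError("weighted metrics require degree vectors, not key nodes")
    if len(kinds) > 1:
        raise ValueError("features must be homogeneous in kind")
    rows = [_values(f).astype(float) for f in features]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"features have mixed lengths {sorted(lengths)}")
    return np.vstack(rows)


def condensed_values(
    M: np.ndarray,
    metric: str,
    *,
    p: float = 2.0,
    log: bool | None = None,
) -> tuple[np.ndarray, str, bool]:
    """Condensed metric values between the rows of a feature matrix.

    Low-level entry point used by :func:`pairwise_distances` and the
    replicated simulation studies. Returns ``(values, name, logged)``.
    """
    metric = metric.lower().replace("-", "_")
    if metric == "log_ks":
        metric = "ks"
    if log is None:
        log = metric == "ks"
    if log and metric != "ks":
        raise ValueError("the log transform is supported for the KS metric only")
    M = np.asarray(M, dtype=float)
    n_p = M.shape[0]
    name = metric
    if metric == "ks":
        vals = pairwise_ks(M)
        if log:
            n_floored = int(np.sum(vals < KS_LOG_FLOOR))
            if n_floored:
                logger.info("floored %d zero KS statistics before log", n_floored)
            vals = np.log(np.maximum(vals, KS_LOG_FLOOR))
            name = "log_ks"
    elif metric in ("jaccard", "jaccard_index"):
        B = M.astype(bool).astype(float)  # float matmul: m11 holds counts
        sizes = B.sum(axis=1)
        m11 = B @ B.T
        union = sizes[:, None] + sizes[None, :] - m11
        iu = np.triu_indices(n_p, k=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            jd = np.where(
                union > 0, (union - m11) / np.where(union > 0, union, 1.0), 0.0
            )
        vals = jd[iu]
        if metric == "jaccard_index":
            vals = 1.0 - vals
    elif metric == "euclidean":
        vals = pdist(M, metric="euclidean")
    elif metric == "minkowski":
        if p < 1:
            raise ValueError(f"Minkowski order must satisfy p >= 1, got {p}")
        vals = pdist(M, metric="minkowski", p=p)
        name = f"minkowski_p{p:g}"
    elif metric == "canberra":
        vals = pdist(M, metric="canberra")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return vals, name, bool(log and metric == "ks")


def pairwise_distances(
    features: Sequence,
    metric: str = "euclidean",
    *,
    p: float = 2.0,
    log: bool | None = None,
    index: PairIndex | None = None,
) -> PairwiseVector:
    """Apply a metric to every unordered pair of subjects.

    Parameters
    ----------
    features : sequence of DegreeVector / KeyNodeVector / array
        One nodal feature vector per subject, homogeneous in kind and length.
    metric : {"ks", "jaccard", "jaccard_index", "euclidean", "minkowski", "canberra"}
    p : Minkowski order (only for ``metric="minkowski"``).
    log : apply the natural-log transform. Defaults to True for "ks"
        (the only metric that benefits from it) and False otherwise.
    index : optional PairIndex carrying subject ids; must match len(features).

    Returns
    -------
    PairwiseVector in condensed (i<j lexicographic) order.
    """
    key = metric.lower().replace("-", "_")
    if key == "log_ks":
        key = "ks"
    binary = key in _BINARY_METRICS
    if key not in _WEIGHTED_METRICS and not binary:
        raise ValueError(f"unknown metric {metric!r}")
    M = _feature_matrix(features, binary=binary)
    n_p = M.shape[0]
    if index is None:
        ids = [
            f.subject_id if isinstance(f, (DegreeVector, KeyNodeVector)) else str(k)
            for k, f in enumerate(features)
        ]
        index = PairIndex(n_p, tuple(ids))
    elif index.n_p != n_p:
        raise ValueError("index does not match the number of subjects")

    vals, name, logged = condensed_values(M, key, p=p, log=log)
    return PairwiseVector(
        values=vals,
        index=index,
        metric_name=name,
        transform="log" if logged else "none",
    )
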