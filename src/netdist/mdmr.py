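"""Multivariate distance matrix regression (MDMR), permutation variant.

MDMR tests the association between a participant-level predictor and a
square matrix of inter-participant distances: the distance matrix is
Gower-centered (McArdle-Anderson), and a pseudo-F compares the trace
explained by the full participant-level design against the reduced design
without the covariate of interest. Significance comes from jointly
permuting participant rows/columns of the distance matrix.

This is the external comparator to the pairwise regression framework; it
consumes *raw* distances (KS without the log transform, Jaccard distance,
Euclidean), since the log transform is a regression-framework device.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform

from .inference import RegressionResult, _check_rank
from .pairs import PairwiseVector

__all__ = ["to_square", "gower_center", "mdmr_permutation_test", "participant_design"]


def to_square(dist) -> np.ndarray:
    """Square symmetric distance matrix from a condensed pairwise vector."""
    if isinstance(dist, PairwiseVector):
        if dist.transform == "log":
            raise ValueError(
                "MDMR consumes raw distances; exponentiate or recompute the "
                "metric without the log transform"
            )
        v = dist.values
    else:
        v = np.asarray(dist, dtype=float)
    if np.any(v < 0):
        raise ValueError("distances must be non-negative")
    return squareform(v)


def gower_center(D: np.ndarray) -> np.ndarray:
    """Gower's doubly centered matrix G = H (-1/2 D*D) H, H = I - J/n.

    For a Euclidean distance matrix computed from points, G equals the
    centered Gram (inner-product) matrix of those points. Every row and
    column of G sums to zero.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max() > 1e-10 or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    A = -0.5 * D * D
    n = D.shape[0]
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    return A - row_mean - col_mean + A.mean()


def participant_design(cov) -> tuple[np.ndarray, tuple]:
    """Participant-level design [intercept, covariates...] from a CovariateTable.

    Continuous covariates enter as-is; categorical ones as integer codes
    (binary indicator for two levels).
    """
    import pandas as pd

    cols = [np.ones(len(cov.data))]
    names = ["intercept"]
    for name in cov.continuous + cov.categorical:
        s = cov.data[name]
        if name in cov.continuous:
            cols.append(s.to_numpy(dtype=float))
        else:
            cols.append(pd.factorize(s, sort=True)[0].astype(float))
        names.append(name)
    return np.column_stack(cols), tuple(names)


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def mdmr_pseudo_f(G: np.ndarray, Xp: np.ndarray, k_coi: int) -> float:
    """Pseudo-F for column ``k_coi`` of the participant design.

    [tr(H_full G) - tr(H_red G)] / [tr((I - H_full) G) / (n_p - p_full)],
    using tr(HGH) = tr(HG) for idempotent H.
    """
    n_p, p_full = Xp.shape
    H_full = _hat(Xp)
    H_red = _hat(np.delete(Xp, k_coi, axis=1))
    num = np.sum(H_full * G) - np.sum(H_red * G)
    resid_tr = np.trace(G) - np.sum(H_full * G)
    denom = resid_tr / (n_p - p_full)
    if denom <= 0:
        return np.inf if num > 0 else 0.0
    return float(num / denom)


def mdmr_permutation_test(
    D: np.ndarray,
    Xp: np.ndarray,
    coi,
    n_permutations: int = 999,
    seed=None,
    columns: tuple | None = None,
) -> RegressionResult:
    """Permutation MDMR test for one covariate of interest.

    ``D`` is the participant distance matrix, ``Xp`` the participant-level
    design (intercept first). The null distribution of the pseudo-F comes
    from jointly permuting participant rows and columns of ``D``.
    ``coi`` may be a column index or, with ``columns`` given, a name.
    p-value: ``(1 + #{F* >= F_obs}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations for usable resolution")
    D = np.asarray(D, dtype=float)
    Xp = np.asarray(Xp, dtype=float)
    if D.shape[0] != Xp.shape[0]:
        raise ValueError("distance matrix and participant design misaligned")
    if columns is not None and isinstance(coi, str):
        k = list(columns).index(coi)
    else:
        k = int(coi)
    names = tuple(columns) if columns is not None else tuple(
        f"x{j}" for j in range(Xp.shape[1])
    )
    _check_rank(Xp, names)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_p, p_full = Xp.shape

    G = gower_center(D)
    H_full = _hat(Xp)
    H_red = _hat(np.delete(Xp, k, axis=1))
    trG = np.trace(G)

    def pseudo_f(Gp):
        num = np.sum(H_full * Gp) - np.sum(H_red * Gp)
        denom = (np.trace(Gp) - np.sum(H_full * Gp)) / (n_p - p_full)
        if denom <= 0:
            return np.inf if num > 0 else 0.0
        return num / denom

    f_obs = pseudo_f(G)
    exceed = 0
    for _ in range(n_permutations):
        pi = rng.permutation(n_p)
        Gp = G[np.ix_(pi, pi)]
        if pseudo_f(Gp) >= f_obs:
            exceed += 1
    p_value = (1 + exceed) / (n_permutations + 1)
    return RegressionResult(
        beta={},
        se={},
        statistic=float(f_obs),
        df=(1, n_permutations),
        p_value=p_value,
        method="mdmr-perm",
        coi=names[k],
        extras={"n_permutations": n_permutations, "trace_G": float(trG)},
    )
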