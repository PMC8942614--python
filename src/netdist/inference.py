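"""Estimation and inference for the pairwise distance regression.

The model relates a condensed vector of pairwise network distances to
pairwise covariate differences,

    Dist_ij = X_ij,con' b_con + X_ij,coi' b_coi + e_ij,

and tests H0: b_coi = 0. Observations sharing a participant are correlated,
so four procedures are provided:

* ``f_test`` — the standard partial F test, valid only under independent
  errors; included as a baseline.
* ``f_test_ile`` — partial F after adding one fixed effect per participant
  (individual-level effects), which absorbs subject-level correlation.
* ``fgls_test`` — feasible generalized least squares under a dyadic
  covariance restriction: residuals of two pairs covary iff the pairs share
  exactly one participant. Both parameters (variance, shared-participant
  covariance) are moment-estimated from OLS residuals in a single feasible
  step, and the GLS solve exploits the structure in closed form.
* ``freedman_lane_test`` — Freedman-Lane permutation of reduced-model
  residuals, permuting *participant* labels (not rows) so the dyadic
  dependence pattern is preserved under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignMatrix
from .pairs import PairwiseVector

__all__ = [
    "RegressionResult",
    "OLSFit",
    "ols_fit",
    "f_test",
    "f_test_ile",
    "fgls_test",
    "freedman_lane_test",
]

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10


@dataclass
class RegressionResult:
    """Outcome of one test of H0: b_coi = 0."""

    beta: dict
    se: dict
    statistic: float
    df: tuple
    p_value: float
    method: str
    coi: str
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coi": self.coi,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "beta": self.beta,
            "se": self.se,
            **{k: v for k, v in self.extras.items() if np.isscalar(v)},
        }


@dataclass
class OLSFit:
    beta: np.ndarray
    residuals: np.ndarray
    rss: float
    df_resid: int
    columns: tuple


def _as_y(y) -> np.ndarray:
    if isinstance(y, PairwiseVector):
        return y.values
    return np.asarray(y, dtype=float)


def _check_rank(X: np.ndarray, columns) -> np.ndarray:
    """QR-based rank check; names the dependent columns on failure."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = np.where(diag <= _RANK_TOL * max(scale, 1.0))[0]
    if bad.size:
        names = [columns[k] for k in bad]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {names}")
    return Q


def ols_fit(y, X: DesignMatrix) -> OLSFit:
    """Ordinary least squares on a pairwise design.

    Requires more observations than columns and a full-column-rank design;
    residuals are orthogonal to the design columns.
    """
    yv = _as_y(y)
    M = X.values
    n, p = M.shape
    if len(yv) != n:
        raise ValueError("response length does not match design")
    if n <= p:
        raise ValueError(f"need n > p; got n={n}, p={p}")
    _check_rank(M, X.columns)
    beta, _, _, _ = np.linalg.lstsq(M, yv, rcond=None)
    resid = yv - M @ beta
    rss = float(resid @ resid)
    return OLSFit(beta, resid, rss, n - p, X.columns)


def _partial_f(yv: np.ndarray, X: DesignMatrix, coi: str) -> tuple:
    """Partial F for the coi column: full-vs-reduced RSS comparison."""
    full = ols_fit(yv, X)
    reduced = ols_fit(yv, X.drop(coi))
    df_full = full.df_resid
    scale = float(yv @ yv)
    if full.rss <= 1e-12 * max(scale, 1.0):
        # (near-)perfect fit: the F ratio is 0/0 noise; the coi contributes
        # only if the reduced model fits measurably worse
        fstat = np.inf if reduced.rss > 1e-12 * max(scale, 1.0) else 0.0
    else:
        fstat = (reduced.rss - full.rss) / (full.rss / df_full)
    fstat = max(float(fstat), 0.0)
    p = float(stats.f.sf(fstat, 1, df_full))
    return full, fstat, df_full, max(p, np.finfo(float).tiny)


def _named(fit: OLSFit, se: np.ndarray, skip_ile: bool = True) -> tuple[dict, dict]:
    beta = {}
    ses = {}
    for name, b, s in zip(fit.columns, fit.beta, se):
        if skip_ile and name.startswith("ile:"):
            continue
        beta[name] = float(b)
        ses[name] = float(s)
    return beta, ses


def _ols_se(X: np.ndarray, rss: float, df: int) -> np.ndarray:
    XtX_inv = np.linalg.inv(X.T @ X)
    return np.sqrt(np.maximum(np.diag(XtX_inv), 0.0) * rss / df)


def f_test(y, X: DesignMatrix, coi: str) -> RegressionResult:
    """Standard partial F test for the covariate of interest.

    Valid only if the pairwise errors were independent; included as the
    baseline comparator (it is anti-conservative for continuous covariates
    because pairs sharing a participant are correlated).
    """
    yv = _as_y(y)
    if coi not in X.columns:
        raise ValueError(f"column {coi!r} not in design")
    full, fstat, df_full, p = _partial_f(yv, X, coi)
    se = _ols_se(X.values, full.rss, df_full)
    beta, ses = _named(full, se)
    return RegressionResult(
        beta, ses, fstat, (1, df_full), p, method="f", coi=coi
    )


def f_test_ile(y, X: DesignMatrix, coi: str) -> RegressionResult:
    """Partial F test with individual-level fixed effects.

    The design must carry the ILE block (one indicator column per
    participant; intercept dropped). The subject effects absorb the
    correlation among pairs sharing a participant, so the residual F test
    for the coi is approximately valid. Identical to the Frisch-Waugh-Lovell
    route of residualizing y and the coi column on [ILE + confounders].
    """
    if X.n_ile == 0:
        raise ValueError("f_test_ile requires a design with the ILE block")
    if X.has_intercept:
        raise ValueError("intercept must be dropped when the ILE block is present")
    yv = _as_y(y)
    full, fstat, df_full, p = _partial_f(yv, X, coi)
    se = _ols_se(X.values, full.rss, df_full)
    beta, ses = _named(full, se)
    return RegressionResult(
        beta, ses, fstat, (1, df_full), p, method="ile", coi=coi
    )


# ---------------------------------------------------------------------------
# FGLS with dyadic covariance
# ---------------------------------------------------------------------------


@dataclass
class DyadicCovariance:
    """Sigma = sigma2 * I + gamma * S, S the share-one-participant adjacency.

    For the pair graph on n_p participants, S has integer eigenvalues
    {2(n_p - 2), n_p - 4, -2}, so positive definiteness is exactly
    -sigma2 / (2 (n_p - 2)) < gamma < sigma2 / 2.
    """

    sigma2: float
    gamma: float
    n_p: int

    def bounds(self) -> tuple[float, float]:
        return (-self.sigma2 / (2 * (self.n_p - 2)), self.sigma2 / 2)

    @property
    def is_pd(self) -> bool:
        lo, hi = self.bounds()
        return self.sigma2 > 0 and lo < self.gamma < hi


def _ile_incidence(index) -> np.ndarray:
    I, J = index.members
    n = index.n_pairs
    B = np.zeros((n, index.n_p))
    rows = np.arange(n)
    B[rows, I] = 1.0
    B[rows, J] = 1.0
    return B


def _dyadic_solve(V: np.ndarray, cov: DyadicCovariance, B: np.ndarray) -> np.ndarray:
    """Sigma^{-1} V via the Woodbury identity on Sigma = a I + gamma B B'.

    ``a = sigma2 - 2 gamma`` and ``B'B = (n_p - 2) I + J`` give a closed
    form; cost is O(n * n_p) per column instead of a dense n x n solve.
    """
    a = cov.sigma2 - 2 * cov.gamma
    if abs(cov.gamma) < 1e-14 * cov.sigma2:
        return V / cov.sigma2
    n_p = cov.n_p
    single = V.ndim == 1
    if single:
        V = V[:, None]
    BtV = B.T @ V  # n_p x k
    c = a / cov.gamma + n_p - 2  # M = c I + J
    W = (BtV - BtV.sum(axis=0, keepdims=True) / (c + n_p)) / c
    out = (V - B @ W) / a
    return out[:, 0] if single else out


def estimate_dyadic_covariance(residuals: np.ndarray, index, df_resid: int | None = None) -> DyadicCovariance:
    """Method-of-moments estimate of the dyadic residual covariance.

    ``sigma2`` is the residual variance (RSS over residual df when given);
    ``gamma`` is the average product of residuals over all observation pairs
    sharing exactly one participant, computed via the identity
    e'Se = ||B'e||^2 - 2||e||^2. Gamma is clipped into the open positive
    definite interval when the raw estimate falls outside it.
    """
    e = np.asarray(residuals, dtype=float)
    n_p = index.n_p
    if n_p < 4:
        raise ValueError("dyadic covariance estimation needs at least 4 participants")
    sq = float(e @ e)
    sigma2 = sq / (df_resid if df_resid else len(e))
    I, J = index.members
    s = np.zeros(n_p)
    np.add.at(s, I, e)
    np.add.at(s, J, e)
    ese = float(s @ s) - 2 * sq
    n_sharing = n_p * (n_p - 1) * (n_p - 2)  # ordered pairs sharing one subject
    gamma = ese / n_sharing
    cov = DyadicCovariance(sigma2, gamma, n_p)
    lo, hi = cov.bounds()
    if not (lo < gamma < hi):
        clipped = float(np.clip(gamma, 0.999 * lo, 0.999 * hi))
        logger.warning(
            "dyadic gamma %.4g outside PD interval (%.4g, %.4g); clipped to %.4g",
            gamma, lo, hi, clipped,
        )
        cov = DyadicCovariance(sigma2, clipped, n_p)
        if not cov.is_pd:
            raise ValueError(
                f"dyadic covariance not positive definite after clipping "
                f"(sigma2={sigma2:.4g}, gamma={gamma:.4g})"
            )
    return cov


def fgls_test(y, X: DesignMatrix, coi: str, *, gamma: float | None = None) -> RegressionResult:
    """Feasible GLS under the dyadic covariance restriction.

    One feasible step: (1) OLS residuals; (2) moment estimates of
    ``sigma2`` and the shared-participant covariance ``gamma``;
    (3) GLS estimate with the structured Sigma and a Wald F test on the
    covariate of interest against F(1, n - p).

    ``gamma`` may be forced (e.g. to 0, which reproduces the OLS partial F
    exactly); otherwise it is estimated from the residuals.
    """
    if X.n_ile:
        raise ValueError("fgls_test expects the non-ILE design (intercept included)")
    if not X.has_intercept:
        raise ValueError("fgls_test requires an intercept in the design")
    if coi not in X.columns:
        raise ValueError(f"column {coi!r} not in design")
    yv = _as_y(y)
    fit = ols_fit(yv, X)
    cov = estimate_dyadic_covariance(fit.residuals, X.index, df_resid=fit.df_resid)
    if gamma is not None:
        cov = DyadicCovariance(cov.sigma2, float(gamma), X.index.n_p)
        if not cov.is_pd:
            raise ValueError(
                f"forced gamma={gamma} leaves Sigma non positive definite "
                f"(sigma2={cov.sigma2:.4g})"
            )
    B = _ile_incidence(X.index)
    M = X.values
    SiX = _dyadic_solve(M, cov, B)
    A = M.T @ SiX  # X' Sigma^-1 X
    b = SiX.T @ yv
    A_inv = np.linalg.inv(A)
    beta = A_inv @ b
    k = X.columns.index(coi)
    var_coi = A_inv[k, k]
    fstat = float(beta[k] ** 2 / var_coi)
    n, p = M.shape
    df = (1, n - p)
    pval = float(stats.f.sf(fstat, 1, n - p))
    se = np.sqrt(np.maximum(np.diag(A_inv), 0.0))
    names_beta = {c: float(v) for c, v in zip(X.columns, beta)}
    names_se = {c: float(v) for c, v in zip(X.columns, se)}
    return RegressionResult(
        names_beta,
        names_se,
        fstat,
        df,
        max(pval, np.finfo(float).tiny),
        method="fgls",
        coi=coi,
        extras={"sigma2": cov.sigma2, "gamma": cov.gamma},
    )


# ---------------------------------------------------------------------------
# Freedman-Lane permutation
# ---------------------------------------------------------------------------


def _fwl_parts(yv: np.ndarray, X: DesignMatrix, coi: str):
    """Residualize y and the coi column on the reduced design (QR-based)."""
    k = X.columns.index(coi)
    Z = np.delete(X.values, k, axis=1)
    x = X.values[:, k]
    Q = _check_rank(Z, tuple(c for c in X.columns if c != coi))
    y_res = yv - Q @ (Q.T @ yv)
    x_res = x - Q @ (Q.T @ x)
    xx = float(x_res @ x_res)
    if xx <= _RANK_TOL * max(float(x @ x), 1.0):
        raise ValueError(f"coi column {coi!r} is collinear with the reduced design")
    return Q, x_res, xx, y_res


def _fwl_f(x_res: np.ndarray, xx: float, y_res: np.ndarray, df: int) -> float:
    num = float(x_res @ y_res) ** 2 / xx
    denom = float(y_res @ y_res) - num
    if denom <= 0:
        return np.inf
    return num / (denom / df)


def freedman_lane_test(
    y,
    X: DesignMatrix,
    coi: str,
    n_permutations: int = 999,
    seed=None,
    *,
    permute_rows: bool = False,
) -> RegressionResult:
    """Freedman-Lane permutation test for the covariate of interest.

    The reduced model (all columns but the coi) is fitted once; its fitted
    values are held fixed while its residuals are permuted to build the null
    distribution of the partial F. Residuals are permuted by relabeling
    *participants*: a permutation pi of the subjects maps the residual of
    pair (i, j) to pair (pi(i), pi(j)). This preserves the exchangeability
    structure of dyadic observations; plain row shuffling (available via
    ``permute_rows=True`` for demonstration) does not and is not valid here.

    p-value: ``(1 + #{F* >= F_obs}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations for usable resolution")
    yv = _as_y(y)
    if coi not in X.columns:
        raise ValueError(f"column {coi!r} not in design")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, p = X.values.shape
    df = n - p
    Q, x_res, xx, y_res = _fwl_parts(yv, X, coi)
    f_obs = _fwl_f(x_res, xx, y_res, df)
    # reduced-model residuals; fitted values are invariant under the scheme
    e = yv - Q @ (Q.T @ yv)

    index = X.index
    n_p = index.n_p
    I, J = index.members
    # row offset of pair (lo, hi): offsets[lo] + hi - lo - 1
    lo_range = np.arange(n_p, dtype=np.int32)
    offsets = (lo_range * (2 * n_p - lo_range - 1) // 2 - lo_range - 1).astype(np.int32)
    B = n_permutations
    exceed = 0
    batch = 256
    done = 0
    while done < B:
        nb = min(batch, B - done)
        if permute_rows:
            idx = np.argsort(rng.random((nb, n)), axis=1)
        else:
            # one subject-label permutation per row, applied to both pair members
            P = np.argsort(rng.random((nb, n_p)), axis=1).astype(np.int32)
            a = P[:, I]
            b = P[:, J]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            idx = offsets[lo] + hi
        E = e[idx]  # nb x n permuted residual sets
        R = E - (E @ Q) @ Q.T  # residualize on reduced design
        num = (R @ x_res) ** 2 / xx
        rr = np.einsum("ij,ij->i", R, R)
        denom = (rr - num) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.inf)
        exceed += int(np.sum(f_star >= f_obs))
        done += nb
    p_value = (1 + exceed) / (B + 1)

    full = ols_fit(yv, X)
    se = _ols_se(X.values, full.rss, full.df_resid)
    beta, ses = _named(full, se)
    return RegressionResult(
        beta,
        ses,
        float(f_obs),
        (1, B),
        p_value,
        method="perm",
        coi=coi,
        extras={"n_permutations": B, "permute_rows": permute_rows, "df_resid": df},
    )
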