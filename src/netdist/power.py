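"""Replicated rejection-rate (type-I error / power) studies.

For every cell of the factorial grid — simulation scenario x distance metric
x inference method x covariate x signal percent — the runner draws fresh
covariates and network data from a seeded substream, pushes them through
features -> distances -> pairwise design -> test, and records the fraction
of p-values below alpha. AGE and SEX never enter the generators, so their
rows estimate type I error; IQ and TRT rows estimate power.

Replicate substreams are keyed by (master seed, sim, signal percent,
replicate), so a cell's data is identical across configurations and runs
with the same master seed; results are bit-reproducible for a fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.linalg import cho_factor, cho_solve

from . import simulate
from .design import CovariateTable, build_design
from .features import key_nodes
from .inference import fgls_test, freedman_lane_test
from .mdmr import mdmr_permutation_test, participant_design, to_square
from .metrics import condensed_values

__all__ = ["StudyConfig", "run_study", "signal_threshold"]

logger = logging.getLogger(__name__)

VALID_METRICS = ("log_ks", "ks", "jaccard", "jaccard_index", "euclidean", "minkowski", "canberra")
VALID_METHODS = ("f", "ile", "fgls", "perm", "mdmr-perm")
_BINARY = ("jaccard", "jaccard_index")


@dataclass(frozen=True)
class StudyConfig:
    """Factorial layout and sampling sizes for one rejection-rate study."""

    sims: tuple = (1,)
    metrics: tuple = ("log_ks", "jaccard", "euclidean")
    methods: tuple = ("ile",)
    covariates: tuple = ("AGE", "SEX", "TRT", "IQ")
    signal_grid: tuple = tuple(np.round(np.arange(0, 1.01, 0.1), 2))
    replicates: int = 200
    alpha: float = 0.05
    seed: int = 0
    n_permutations: int = 500
    n_subjects: int = 100
    n_nodes: int = simulate.N_NODES
    key_fraction: float = 0.2
    minkowski_p: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "sims", tuple(int(s) for s in self.sims))
        object.__setattr__(self, "metrics", tuple(self.metrics))
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "signal_grid", tuple(float(s) for s in self.signal_grid)
        )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for s in self.signal_grid:
            if not (0 <= s <= 1):
                raise ValueError(f"signal grid values must be in [0, 1], got {s}")
        for m in self.metrics:
            if m not in VALID_METRICS:
                raise ValueError(f"unknown metric {m!r}; choose from {VALID_METRICS}")
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {VALID_METHODS}")
        for s in self.sims:
            if s not in (1, 2, 3, 4):
                raise ValueError(f"unknown simulation id {s}")
        for c in self.covariates:
            if c not in ("AGE", "SEX", "TRT", "IQ"):
                raise ValueError(f"unknown covariate {c!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


_COVARIATE_ORDER = ("AGE", "SEX", "TRT", "IQ")


def _perm_rng(entropy: tuple, method: str, covariate: str) -> np.random.Generator:
    """Permutation substream keyed by (replicate, method, covariate)."""
    key = entropy + (
        1000 + VALID_METHODS.index(method),
        _COVARIATE_ORDER.index(covariate),
    )
    return np.random.default_rng(np.random.SeedSequence(key))


def _partial_f_all(y: np.ndarray, X, test_cols) -> dict:
    """Partial F p-value for each tested column of a full-model fit (t^2)."""
    M = X.values
    n, p = M.shape
    G = M.T @ M
    cho = cho_factor(G)
    beta = cho_solve(cho, M.T @ y)
    resid = y - M @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    G_inv = cho_solve(cho, np.eye(p))
    out = {}
    for name in test_cols:
        k = X.columns.index(name)
        f = beta[k] ** 2 / (sigma2 * G_inv[k, k])
        out[name] = float(_stats.f.sf(f, 1, df))
    return out


def _replicate_pvalues(degrees: np.ndarray, cov: pd.DataFrame, config: StudyConfig, entropy: tuple) -> dict:
    """p-values for every (metric, method, covariate) cell of one replicate.

    Permutation draws use a substream keyed by (method, covariate) but not by
    metric, so the JD and JI (and any other metric pair) see identical
    permutations — required for their exact p-value equivalence.
    """
    table = CovariateTable(
        cov, continuous=("AGE", "IQ"), categorical=("SEX", "TRT"), coi="IQ"
    )
    X_int = build_design(table, include_intercept=True)
    needs_ile = "ile" in config.methods
    X_ile = build_design(table, include_ile=True) if needs_ile else None
    needs_mdmr = "mdmr-perm" in config.methods
    Xp, xp_names = participant_design(table) if needs_mdmr else (None, None)

    key_matrix = None
    if any(m in _BINARY for m in config.metrics):
        key_matrix = np.vstack(
            [key_nodes(row, config.key_fraction).values for row in degrees]
        )

    out = {}
    for metric in config.metrics:
        feats = key_matrix if metric in _BINARY else degrees
        y, _, _ = condensed_values(feats, metric, p=config.minkowski_p)
        raw = None
        if needs_mdmr:
            # MDMR consumes raw distances (no log transform)
            raw, _, _ = condensed_values(feats, metric, p=config.minkowski_p, log=False)
        for method in config.methods:
            if method == "f":
                ps = _partial_f_all(y, X_int, config.covariates)
            elif method == "ile":
                ps = _partial_f_all(y, X_ile, config.covariates)
            elif method == "fgls":
                ps = {
                    c: fgls_test(y, X_int, c).p_value for c in config.covariates
                }
            elif method == "perm":
                ps = {
                    c: freedman_lane_test(
                        y, X_int, c, config.n_permutations, _perm_rng(entropy, method, c)
                    ).p_value
                    for c in config.covariates
                }
            elif method == "mdmr-perm":
                D = to_square(raw)
                ps = {
                    c: mdmr_permutation_test(
                        D, Xp, c, config.n_permutations,
                        _perm_rng(entropy, method, c), columns=xp_names
                    ).p_value
                    for c in config.covariates
                }
            for c, p in ps.items():
                out[(metric, method, c)] = p
    return out


def run_study(config: StudyConfig) -> pd.DataFrame:
    """Run the factorial rejection-rate study.

    Returns a long-format table with one row per (sim, metric, method,
    covariate, s_p): the rejection rate (fraction of replicate p-values
    below alpha), the number of successful replicates, the binomial Monte
    Carlo standard error, and the count of excluded (failed) replicates.
    """
    rows = []
    for sim in config.sims:
        for s_p in config.signal_grid:
            sp_key = int(round(s_p * 1000))
            counts: dict = {}
            n_ok = 0
            n_failed = 0
            for rep in range(config.replicates):
                entropy = (config.seed, sim, sp_key, rep)
                rng = np.random.default_rng(np.random.SeedSequence(entropy))
                try:
                    cov = simulate.simulate_covariates(config.n_subjects, rng)
                    degrees = simulate.degrees_for_replicate(
                        sim, cov, s_p, rng, config.n_nodes
                    )
                    pvals = _replicate_pvalues(degrees, cov, config, entropy)
                except Exception:
                    n_failed += 1
                    logger.exception(
                        "replicate failed (seed=%s, sim=%s, s_p=%s, rep=%s); excluded",
                        config.seed, sim, s_p, rep,
                    )
                    continue
                n_ok += 1
                for cell, p in pvals.items():
                    counts[cell] = counts.get(cell, 0) + (p < config.alpha)
            if n_failed:
                logger.warning(
                    "sim %s s_p %s: excluded %d of %d replicates",
                    sim, s_p, n_failed, config.replicates,
                )
            for (metric, method, covariate), k in sorted(counts.items()):
                rate = k / n_ok if n_ok else np.nan
                rows.append(
                    {
                        "sim": sim,
                        "metric": metric,
                        "method": method,
                        "covariate": covariate,
                        "s_p": s_p,
                        "rejection_rate": rate,
                        "replicates": n_ok,
                        "mc_se": float(np.sqrt(rate * (1 - rate) / n_ok))
                        if n_ok
                        else np.nan,
                        "n_failed": n_failed,
                    }
                )
    return pd.DataFrame(rows)


def signal_threshold(
    table: pd.DataFrame,
    sim: int,
    metric: str,
    method: str,
    covariate: str,
    level: float = 0.8,
    grid=None,
):
    """Smallest grid signal percent whose rejection rate reaches ``level``.

    The rule is *first crossing*: power can dip back below the level at
    higher signal (observed for the Jaccard metrics), and such dips do not
    revoke an earlier crossing. Returns ``None`` if the level is never
    reached. Raises if the table does not cover the requested grid.
    """
    sel = table[
        (table["sim"] == sim)
        & (table["metric"] == metric)
        & (table["method"] == method)
        & (table["covariate"] == covariate)
    ].sort_values("s_p")
    if sel.empty:
        raise ValueError(
            f"no rows for sim={sim}, metric={metric}, method={method}, "
            f"covariate={covariate}"
        )
    if grid is not None:
        have = set(np.round(sel["s_p"].to_numpy(), 6))
        want = set(np.round(np.asarray(list(grid), dtype=float), 6))
        if not want <= have:
            raise ValueError(f"table missing grid points {sorted(want - have)}")
        sel = sel[np.isin(np.round(sel["s_p"], 6), sorted(want))]
    hit = sel[sel["rejection_rate"] >= level]
    if hit.empty:
        return None
    return float(hit["s_p"].iloc[0])
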