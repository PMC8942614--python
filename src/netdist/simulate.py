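"""Synthetic study generators: covariates, Beta-block connectomes, degree vectors.

Four scenarios, each with 100 subjects by default:

* **Simulations 1-3** draw 268 x 268 symmetric connectivity matrices whose
  entries come from three Beta distributions: a low-connectivity noise
  distribution Beta(4/3, 6) everywhere, a high-connectivity noise block
  Beta(4, 6) shared by all subjects, and a covariate-dependent signal block
  Beta(s_p * a_i + (1 - s_p) * 4/3, 6), where ``s_p`` is the signal percent
  and ``a_i = max(4/3, 4 + 0.2 (IQ_i - 100) + 6 * 1{treatment})`` is the
  subject's covariate-dependent shape parameter. At ``s_p = 0`` the signal
  block is distributionally identical to the low-noise background. The three
  scenarios differ only in block geometry:

  - Sim 1: one 15x15 high block (nodes 0-14), one 15x15 signal block (15-29);
  - Sim 2: the signal region becomes the border of a combined 21x21 region
    (nodes 0-20) around a centered 15x15 high block (nodes 3-17);
  - Sim 3: Sim 1 plus two extra 15x15 high blocks (nodes 30-44 and 45-59).

  Blocks act on node *pairs* (both endpoints inside the block's node range);
  the diagonal stays zero. Block placement is immaterial to the
  permutation-invariant metrics, so fixed node indices are used for
  reproducibility.

* **Simulation 4** skips matrices and draws iid Normal(100 + s_p * a_i, 1)
  degree vectors of length 268 directly, probing sensitivity to
  distributional (rather than spatial) differences.

Covariates: SEX is a fair coin per subject; TRT is a uniformly random exact
half split; AGE and IQ are Normal(100, 15^2) rounded to integers. AGE and
SEX never enter the generator, so they are true nulls.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .features import ConnectionMatrix, DegreeVector

__all__ = [
    "SimLayout",
    "layout",
    "simulate_covariates",
    "covariate_parameter",
    "simulate_connectivity",
    "simulate_degree_matrix",
    "simulate_degree_vectors",
    "degrees_for_replicate",
    "LOW_SHAPE",
    "HIGH_SHAPE",
    "BETA_B",
    "N_NODES",
]

LOW_SHAPE = 4.0 / 3.0  # low-connectivity noise: Beta(4/3, 6)
HIGH_SHAPE = 4.0  # high-connectivity noise: Beta(4, 6)
BETA_B = 6.0
N_NODES = 268


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimLayout:
    """Block geometry for one connectivity scenario.

    ``high_blocks`` and the signal region are half-open node ranges; a node
    pair belongs to a block iff both endpoints fall in its range. For the
    border-style signal (Sim 2), the signal region is ``signal_outer`` minus
    pairs entirely inside ``signal_inner``.
    """

    sim_id: int
    n_n: int = N_NODES
    high_blocks: tuple = ()
    signal_outer: tuple = None
    signal_inner: tuple = None

    def __post_init__(self):
        spans = list(self.high_blocks)
        if self.signal_outer is not None:
            spans.append(self.signal_outer)
        top = max((b for _, b in spans), default=0)
        if top > self.n_n:
            raise ValueError(f"layout blocks exceed n_n={self.n_n}")


_LAYOUTS = {
    1: dict(high_blocks=((0, 15),), signal_outer=(15, 30)),
    2: dict(high_blocks=((3, 18),), signal_outer=(0, 21), signal_inner=(3, 18)),
    3: dict(high_blocks=((0, 15), (30, 45), (45, 60)), signal_outer=(15, 30)),
}


def layout(sim_id: int, n_n: int = N_NODES) -> SimLayout:
    """Block layout for connectivity Simulations 1-3."""
    if sim_id not in _LAYOUTS:
        raise ValueError(f"connectivity layouts exist for sims 1-3, got {sim_id}")
    return SimLayout(sim_id=sim_id, n_n=n_n, **_LAYOUTS[sim_id])


@lru_cache(maxsize=8)
def _edge_groups(lay: SimLayout):
    """Upper-triangle edge indices split into (low, high, signal) groups.

    Returns (I, J, slices) where the concatenated endpoint arrays are grouped
    contiguously and ``slices`` maps group name to its slice.
    """
    I, J = np.triu_indices(lay.n_n, k=1)

    def in_span(span):
        a, b = span
        return (I >= a) & (I < b) & (J >= a) & (J < b)

    high = np.zeros(len(I), dtype=bool)
    for span in lay.high_blocks:
        high |= in_span(span)
    signal = np.zeros(len(I), dtype=bool)
    if lay.signal_outer is not None:
        signal = in_span(lay.signal_outer)
        if lay.signal_inner is not None:
            signal &= ~in_span(lay.signal_inner)
    if np.any(high & signal):
        raise ValueError("high and signal blocks overlap")
    low = ~(high | signal)

    order = np.concatenate([np.where(low)[0], np.where(high)[0], np.where(signal)[0]])
    n_low, n_high, n_sig = int(low.sum()), int(high.sum()), int(signal.sum())
    slices = {
        "low": slice(0, n_low),
        "high": slice(n_low, n_low + n_high),
        "signal": slice(n_low + n_high, n_low + n_high + n_sig),
    }
    return I[order], J[order], slices


def simulate_covariates(n_p: int = 100, seed=None) -> pd.DataFrame:
    """Subject covariate table: SEX, TRT, AGE, IQ.

    SEX is iid Bernoulli(1/2) ("female"/"male"); TRT is a uniformly random
    exact half split ("treatment"/"placebo"), requiring even ``n_p``; AGE and
    IQ are Normal(100, 15^2) rounded to the nearest integer. Subject ids are
    zero-padded so lexicographic order matches generation order.
    """
    if n_p % 2:
        raise ValueError("n_p must be even for an exact half treatment split")
    if n_p < 2:
        raise ValueError("need at least 2 subjects")
    rng = _rng(seed)
    sex = np.where(rng.integers(0, 2, n_p) == 1, "male", "female")
    trt = np.full(n_p, "placebo", dtype=object)
    trt[rng.permutation(n_p)[: n_p // 2]] = "treatment"
    age = np.round(rng.normal(100, 15, n_p)).astype(int)
    iq = np.round(rng.normal(100, 15, n_p)).astype(int)
    width = len(str(n_p))
    ids = [f"S{k + 1:0{width}d}" for k in range(n_p)]
    return pd.DataFrame(
        {"AGE": age, "SEX": sex, "TRT": trt, "IQ": iq},
        index=pd.Index(ids, name="subject_id"),
    )


def covariate_parameter(iq, trt):
    """Covariate-dependent Beta shape a_i = max(4/3, 4 + 0.2 (IQ - 100) + 6 TRT).

    ``trt`` may be boolean/0-1 or the strings used by
    :func:`simulate_covariates` ("treatment"/"placebo").
    """
    iq = np.asarray(iq, dtype=float)
    t = np.asarray(trt)
    if t.dtype.kind in ("U", "S", "O"):
        t = t == "treatment"
    t = t.astype(float)
    a = 4.0 + 0.2 * (iq - 100.0) + 6.0 * t
    return np.maximum(LOW_SHAPE, a)


def _signal_shape(a_i: float, s_p: float) -> float:
    return s_p * a_i + (1.0 - s_p) * LOW_SHAPE


def _edge_weights(lay: SimLayout, a_i: float, s_p: float, rng) -> np.ndarray:
    """Draw all upper-triangle edge weights for one subject, grouped order."""
    _, _, sl = _edge_groups(lay)
    shape_sig = _signal_shape(a_i, s_p)
    if shape_sig <= 0:
        raise ValueError(f"invalid Beta shape {shape_sig} for signal block")
    n_low = sl["low"].stop - sl["low"].start
    n_high = sl["high"].stop - sl["high"].start
    n_sig = sl["signal"].stop - sl["signal"].start
    w = np.empty(n_low + n_high + n_sig)
    w[sl["low"]] = rng.beta(LOW_SHAPE, BETA_B, n_low)
    w[sl["high"]] = rng.beta(HIGH_SHAPE, BETA_B, n_high)
    w[sl["signal"]] = rng.beta(shape_sig, BETA_B, n_sig)
    return w


def _check_sp(s_p: float):
    if not (0.0 <= s_p <= 1.0):
        raise ValueError(f"signal percent must be in [0, 1], got {s_p}")


def simulate_connectivity(lay: SimLayout, covariates: pd.DataFrame, s_p: float, seed=None) -> list:
    """Connectivity matrices for every subject under a block layout.

    Each matrix is symmetric with a zero diagonal; upper-triangle entries are
    drawn from the block-appropriate Beta distribution (the signal block uses
    the subject's ``a_i``) and mirrored.
    """
    _check_sp(s_p)
    rng = _rng(seed)
    I, J, _ = _edge_groups(lay)
    a = covariate_parameter(covariates["IQ"], covariates["TRT"])
    out = []
    for sid, a_i in zip(covariates.index, a):
        w = _edge_weights(lay, float(a_i), s_p, rng)
        W = np.zeros((lay.n_n, lay.n_n))
        W[I, J] = w
        W[J, I] = w
        out.append(ConnectionMatrix(W, subject_id=str(sid)))
    return out


def simulate_degree_matrix(lay: SimLayout, covariates: pd.DataFrame, s_p: float, seed=None) -> np.ndarray:
    """Degree vectors (row sums) for all subjects without storing matrices.

    Consumes the random stream exactly as :func:`simulate_connectivity`, so
    with the same seed the rows equal the degree vectors of the simulated
    matrices. Used by the replicated power studies, where only degrees are
    needed downstream.
    """
    _check_sp(s_p)
    rng = _rng(seed)
    I, J, _ = _edge_groups(lay)
    a = covariate_parameter(covariates["IQ"], covariates["TRT"])
    n_p = len(covariates)
    D = np.empty((n_p, lay.n_n))
    for k, a_i in enumerate(a):
        w = _edge_weights(lay, float(a_i), s_p, rng)
        D[k] = np.bincount(I, weights=w, minlength=lay.n_n) + np.bincount(
            J, weights=w, minlength=lay.n_n
        )
    return D


def simulate_degree_vectors(covariates: pd.DataFrame, s_p: float, seed=None, n_n: int = N_NODES) -> list:
    """Simulation 4: iid Normal(100 + s_p * a_i, 1) degree vectors per subject.

    At ``s_p = 0`` every subject's vector is drawn from Normal(100, 1).
    """
    D = sim4_degree_matrix(covariates, s_p, seed=seed, n_n=n_n)
    return [
        DegreeVector(row, subject_id=str(sid)) for sid, row in zip(covariates.index, D)
    ]


def sim4_degree_matrix(covariates: pd.DataFrame, s_p: float, seed=None, n_n: int = N_NODES) -> np.ndarray:
    _check_sp(s_p)
    rng = _rng(seed)
    a = covariate_parameter(covariates["IQ"], covariates["TRT"])
    means = 100.0 + s_p * a
    return rng.normal(loc=means[:, None], scale=1.0, size=(len(covariates), n_n))


def degrees_for_replicate(sim_id: int, covariates: pd.DataFrame, s_p: float, rng, n_n: int = N_NODES) -> np.ndarray:
    """Degree matrix for one replicate of any scenario (1-3: connectivity row
    sums; 4: direct Normal draws)."""
    if sim_id in (1, 2, 3):
        return simulate_degree_matrix(layout(sim_id, n_n), covariates, s_p, rng)
    if sim_id == 4:
        return sim4_degree_matrix(covariates, s_p, rng, n_n=n_n)
    raise ValueError(f"unknown simulation id {sim_id}")
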