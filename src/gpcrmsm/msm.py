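"""Reversible Markov-state-model estimation and validation.

A Markov state model (MSM) describes discrete-state kinetics through a
row-stochastic transition matrix ``T(τ)`` at lag time τ, propagated via the
Chapman–Kolmogorov relation ``p(nτ) = p(0)·T(τ)ⁿ``.  Estimation here is the
closed-form symmetrized-count (naive reversible) estimator:

    S = (C + Cᵀ)/2,   T_ij = S_ij / Σ_k S_ik,   π_i ∝ Σ_k S_ik

which satisfies detailed balance ``π_i T_ij = π_j T_ji`` exactly by
construction and is adequate for equilibrium-sampled chains.  States outside
the largest connected component of the symmetrized count graph are discarded
(no pseudocounts) and reported with their frame fraction.

Model validation follows standard MSM practice: the Chapman–Kolmogorov test
compares ``T(nτ)`` estimated directly against ``T(τ)ⁿ``, and implied
timescales ``t_k = −τ/ln λ_k`` should be lag-independent for Markovian data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DataError, EstimationError, ModelError, ParameterError
from .features import StateSequence

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "count_transitions",
    "estimate_reversible",
    "stationary_distribution",
    "propagate",
    "ck_test",
    "implied_timescales",
    "timescales_from_matrix",
]


@dataclass
class CountMatrix:
    """Observed i→j transition counts at a fixed lag."""

    C: np.ndarray
    lag: int
    mode: str = "sliding"  # "sliding" | "strided"

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ModelError("count matrix must be square")
        if (self.C < 0).any():
            raise ModelError("count matrix entries must be non-negative")

    @property
    def m(self) -> int:
        return self.C.shape[0]


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with lag time and stationary vector.

    ``active_states`` maps the model's state indices back to the labels of the
    input sequence when disconnected states were discarded.
    """

    T: np.ndarray
    lag: float
    pi: np.ndarray
    active_states: np.ndarray = None
    discarded_frame_fraction: float = 0.0

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.active_states is None:
            self.active_states = np.arange(self.T.shape[0])
        self.active_states = np.asarray(self.active_states, dtype=int)
        if np.abs(self.T.sum(axis=1) - 1.0).max() > 1e-10:
            raise ModelError("transition matrix rows must sum to 1 within 1e-10")
        if (self.pi < -1e-12).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ModelError("stationary distribution must be a probability vector")
        if np.abs(self.pi @ self.T - self.pi).max() > 1e-8:
            raise ModelError("pi is not stationary for T (tolerance 1e-8)")

    @property
    def m(self) -> int:
        return self.T.shape[0]

    def is_reversible(self, tol: float = 1e-10) -> bool:
        flux = self.pi[:, None] * self.T
        return bool(np.abs(flux - flux.T).max() <= tol)


def count_transitions(seq: StateSequence, lag: int = 1, mode: str = "sliding") -> CountMatrix:
    """Count i→j transitions at ``lag`` frames.

    ``sliding`` counts every pair (t, t+lag); ``strided`` counts only
    t ∈ {0, lag, 2·lag, …} for independence-sensitive error estimates.
    """
    if lag < 1:
        raise ParameterError("lag must be >= 1")
    labels = seq.labels
    if labels.size <= lag:
        raise DataError(f"sequence of length {labels.size} too short for lag {lag}")
    if mode == "sliding":
        src, dst = labels[:-lag], labels[lag:]
    elif mode == "strided":
        sub = labels[::lag]
        src, dst = sub[:-1], sub[1:]
    else:
        raise ParameterError(f"unknown counting mode {mode!r}")
    C = np.zeros((seq.m, seq.m))
    np.add.at(C, (src, dst), 1.0)
    return CountMatrix(C, lag=lag, mode=mode)


def estimate_reversible(counts: CountMatrix, frame_interval: float = 1.0) -> TransitionModel:
    """Reversible MSM from transition counts by count symmetrization.

    Restricted to the largest connected component of the symmetrized count
    graph; detailed balance holds exactly by construction.
    """
    C = counts.C
    if C.sum() == 0:
        raise EstimationError("all-zero count matrix")
    S = 0.5 * (C + C.T)
    n_comp, comp = connected_components(csr_matrix(S > 0), directed=False)
    weights = np.array([S[comp == k].sum() for k in range(n_comp)])
    keep_comp = int(np.argmax(weights))
    active = np.flatnonzero(comp == keep_comp)
    discarded = 1.0 - S[np.ix_(active, active)].sum() / S.sum()
    S = S[np.ix_(active, active)]
    rows = S.sum(axis=1)
    if (rows == 0).any():
        raise EstimationError("isolated state inside the selected component")
    T = S / rows[:, None]
    pi = rows / rows.sum()
    return TransitionModel(T, lag=counts.lag * frame_interval, pi=pi,
                           active_states=active,
                           discarded_frame_fraction=float(discarded))


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic, irreducible ``T``.

    Computed as the left eigenvector of eigenvalue 1, normalized to sum 1.
    """
    T = np.asarray(T, dtype=float)
    if np.abs(T.sum(axis=1) - 1.0).max() > 1e-10:
        raise ModelError("T rows must sum to 1")
    n_comp, comp = connected_components(csr_matrix(T > 0), directed=True,
                                        connection="strong")
    if n_comp > 1:
        groups = [np.flatnonzero(comp == k).tolist() for k in range(n_comp)]
        raise ModelError(f"T is reducible; strongly connected components: {groups}")
    w, v = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def propagate(p0: np.ndarray, model: TransitionModel | np.ndarray, n: int) -> np.ndarray:
    """Chapman–Kolmogorov propagation ``p(nτ) = p0 · Tⁿ``."""
    T = model.T if isinstance(model, TransitionModel) else np.asarray(model, float)
    p0 = np.asarray(p0, dtype=float)
    if n < 0:
        raise ParameterError("n must be >= 0")
    if p0.shape != (T.shape[0],):
        raise ModelError(f"p0 has shape {p0.shape}; expected ({T.shape[0]},)")
    if abs(p0.sum() - 1.0) > 1e-10:
        raise ModelError("p0 must sum to 1")
    return p0 @ np.linalg.matrix_power(T, n)


def _mle_transition(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain row-normalized transition estimate on states with observed exits."""
    active = np.flatnonzero(C.sum(axis=1) > 0)
    sub = C[np.ix_(active, active)]
    rows = sub.sum(axis=1)
    if (rows == 0).any():
        raise EstimationError("state with no transitions among active states")
    return sub / rows[:, None], active


def ck_test(seq: StateSequence, lag: int, n_values) -> dict[int, float]:
    """Chapman–Kolmogorov test: ``max|T(n·τ) − T(τ)ⁿ|`` per requested n.

    Both sides use the direct maximum-likelihood (row-normalized count)
    estimate, so deterministic chains validate exactly; a small discrepancy
    indicates the sequence is Markovian at lag τ.
    """
    T1, act1 = _mle_transition(count_transitions(seq, lag).C)
    out: dict[int, float] = {}
    for n in n_values:
        if seq.labels.size <= n * lag:
            raise DataError(f"sequence too short for lag {n * lag} (n = {n})")
        Tn_direct, actn = _mle_transition(count_transitions(seq, n * lag).C)
        shared = np.intersect1d(act1, actn)
        i1 = np.searchsorted(act1, shared)
        i_n = np.searchsorted(actn, shared)
        Tn_pred = np.linalg.matrix_power(T1, n)
        out[int(n)] = float(
            np.abs(Tn_direct[np.ix_(i_n, i_n)] - Tn_pred[np.ix_(i1, i1)]).max())
    return out


def timescales_from_matrix(T: np.ndarray, lag: float = 1.0) -> np.ndarray:
    """Relaxation timescales ``t_k = −lag / ln|λ_k|`` of a transition matrix.

    Eigenvalues are sorted by modulus and the Perron eigenvalue excluded;
    near-unit eigenvalues give infinity, complex ones enter by modulus.
    """
    lam = np.sort(np.abs(np.linalg.eigvals(np.asarray(T, float))))[::-1][1:]
    return np.where(lam >= 1.0 - 1e-12, np.inf,
                    np.where(lam <= 1e-15, 0.0,
                             -lag / np.log(np.clip(lam, 1e-15, 1))))


def implied_timescales(seq: StateSequence, lags) -> dict[int, np.ndarray]:
    """Implied relaxation timescales ``t_k = −lag / ln|λ_k|`` per lag.

    Eigenvalues of T(lag) are sorted by modulus, the Perron eigenvalue λ₁ = 1
    excluded; near-unit eigenvalues report infinity.
    """
    if seq.m < 2:
        raise ParameterError("implied timescales need at least 2 states")
    out: dict[int, np.ndarray] = {}
    for lag in lags:
        model = estimate_reversible(count_transitions(seq, lag))
        out[int(lag)] = timescales_from_matrix(model.T, lag)
    return out
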