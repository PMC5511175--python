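"""Transition-path theory (TPT) on a discrete Markov state model.

Given a transition matrix ``T(τ)`` with stationary distribution π and two
disjoint state sets A (reactant) and B (product):

* the forward committor ``q⁺_i`` is the probability that a trajectory at
  state i reaches B before A; it solves the boundary-value problem
  ``q_i = Σ_j T_ij q_j`` for i ∉ A∪B with q = 0 on A and q = 1 on B;
* the reactive flux is ``f_ij = π_i q⁻_i T_ij q⁺_j`` (i ≠ j), its net part
  ``f⁺_ij = max(f_ij − f_ji, 0)``, and the total reactive flux F is the net
  flux across any cut separating A from B;
* the transition rate per lag time is ``k_AB = F / (τ Σ_i π_i (1 − q⁺_i))``;
* pathways are extracted by iterative bottleneck decomposition of the net
  flux network: repeatedly take the A→B path with the largest
  minimum-edge capacity and subtract that capacity along it.

A brute-force chain-simulation oracle (:func:`simulate_rate_oracle`) provides
an independent check of the rate: it counts completed A→B reactive events per
unit of time the trajectory spends "last in A" (not yet committed to B).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, GpcrMsmError, ModelError, ParameterError
from .msm import TransitionModel
from .synthetic import generate_markov_chain

__all__ = [
    "TPTResult",
    "committor",
    "backward_committor",
    "reactive_flux",
    "rate",
    "shortest_pathways",
    "simulate_rate_oracle",
    "analyze",
]


class SetError(GpcrMsmError, ValueError):
    """Invalid reactant/product state sets."""


class DegenerateRateError(GpcrMsmError, ZeroDivisionError):
    """The rate denominator vanished (all mass committed to B)."""


@dataclass
class TPTResult:
    """Full TPT analysis of an A→B transition."""

    A: tuple[int, ...]
    B: tuple[int, ...]
    q_plus: np.ndarray
    q_minus: np.ndarray
    flux: np.ndarray            # f_ij = pi_i q-_i T_ij q+_j, zero diagonal
    net_flux: np.ndarray        # max(f_ij - f_ji, 0)
    total_flux: float           # F, per tau
    rate: float                 # k_AB, per tau
    pathways: list[tuple[list[int], float]]
    residual_flux: float

    def bottleneck_flux(self) -> float:
        """Capacity of the dominant pathway (0 if none)."""
        return self.pathways[0][1] if self.pathways else 0.0


def _check_sets(m: int, A, B) -> tuple[np.ndarray, np.ndarray]:
    A = np.unique(np.asarray(list(A), dtype=int))
    B = np.unique(np.asarray(list(B), dtype=int))
    if A.size == 0 or B.size == 0:
        raise SetError("A and B must be non-empty")
    if np.intersect1d(A, B).size:
        raise SetError("A and B must be disjoint")
    for s in np.concatenate([A, B]):
        if not (0 <= s < m):
            raise SetError(f"state {s} outside [0, {m})")
    return A, B


def committor(model: TransitionModel | np.ndarray, A, B) -> np.ndarray:
    """Forward committor q⁺: probability of reaching B before A, per state."""
    T = model.T if isinstance(model, TransitionModel) else np.asarray(model, float)
    m = T.shape[0]
    A, B = _check_sets(m, A, B)
    q = np.zeros(m)
    q[B] = 1.0
    interior = np.setdiff1d(np.arange(m), np.concatenate([A, B]))
    if interior.size:
        M = np.eye(interior.size) - T[np.ix_(interior, interior)]
        rhs = T[np.ix_(interior, B)].sum(axis=1)
        try:
            q[interior] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            import warnings

            warnings.warn("singular committor system (no A–B connection); q = 0 off B")
            q[interior] = 0.0
    return np.clip(q, 0.0, 1.0)


def backward_committor(model: TransitionModel, A, B) -> np.ndarray:
    """Backward committor q⁻: probability the trajectory came last from A.

    For a reversible model this is exactly ``1 − q⁺``; the general solve uses
    the time-reversed chain ``T̃_ij = π_j T_ji / π_i``.
    """
    if model.is_reversible():
        return 1.0 - committor(model, A, B)
    pi = model.pi
    if (pi <= 0).any():
        raise ModelError("backward committor needs strictly positive pi")
    T_rev = (pi[None, :] * model.T.T) / pi[:, None]  # T̃_ij = π_j T_ji / π_i
    return committor(T_rev, B, A)  # roles swapped on the reversed chain


def reactive_flux(
    model: TransitionModel,
    q_plus: np.ndarray,
    q_minus: np.ndarray | None = None,
    A=None,
    B=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Reactive flux matrix, its net part, and the total flux F (per τ)."""
    T, pi = model.T, model.pi
    q_plus = np.asarray(q_plus, float)
    if q_plus.shape != (model.m,):
        raise ModelError("committor has wrong dimension")
    if q_minus is None:
        q_minus = 1.0 - q_plus
    f = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    f_net = np.clip(f - f.T, 0.0, None)
    if A is None:
        A = np.flatnonzero(q_plus == 0.0)
    A = np.asarray(list(A), dtype=int)
    notA = np.setdiff1d(np.arange(model.m), A)
    F = float(f_net[np.ix_(A, notA)].sum())
    return f, f_net, F


def rate(F: float, model: TransitionModel, q_plus: np.ndarray) -> float:
    """TPT transition rate ``k_AB = F / (τ Σ_i π_i (1 − q⁺_i))`` in 1/τ units."""
    denom = float(model.pi @ (1.0 - np.asarray(q_plus, float)))
    if denom <= 0.0:
        raise DegenerateRateError("all stationary mass is committed to B")
    return F / (model.lag * denom)


def _widest_path(f_net: np.ndarray, A: np.ndarray, B: np.ndarray):
    """Highest-bottleneck A→B path; ties broken by length then state order.

    Dijkstra-style search with priority (−bottleneck, path length, path).
    Returns (path, bottleneck) or None if no positive-capacity path exists.
    """
    m = f_net.shape[0]
    Bset = set(B.tolist())
    heap = [(-np.inf, 1, (int(a),)) for a in sorted(A.tolist())]
    heapq.heapify(heap)
    best_seen: dict[int, tuple[float, int, tuple]] = {}
    while heap:
        neg_bn, length, path = heapq.heappop(heap)
        node = path[-1]
        key = (neg_bn, length, path)
        if node in best_seen and best_seen[node] <= key:
            continue
        best_seen[node] = key
        if node in Bset:
            return list(path), -neg_bn
        for nxt in range(m):
            cap = f_net[node, nxt]
            if cap <= 0 or nxt in path:
                continue
            bn = min(-neg_bn, cap)
            heapq.heappush(heap, (-bn, length + 1, path + (nxt,)))
    return None


def shortest_pathways(
    f_net: np.ndarray,
    A,
    B,
    max_paths: int = 100,
    tol: float = 1e-12,
) -> tuple[list[tuple[list[int], float]], float]:
    """Iterative bottleneck decomposition of the net reactive flux.

    Repeatedly extracts the A→B path with the largest minimum-edge capacity,
    records (path, capacity), subtracts the capacity along the path, and stops
    when the flux is exhausted or ``max_paths`` is reached.  Returns the
    ranked pathway list and the residual (undecomposed) flux.
    """
    f_net = np.array(f_net, dtype=float, copy=True)
    m = f_net.shape[0]
    A, B = _check_sets(m, A, B)
    scale = max(f_net.max(), 1.0)
    paths: list[tuple[list[int], float]] = []
    for _ in range(max_paths):
        found = _widest_path(f_net, A, B)
        if found is None or found[1] <= tol * scale:
            break
        path, cap = found
        for u, v in zip(path[:-1], path[1:]):
            f_net[u, v] -= cap
        paths.append((path, float(cap)))
    notA = np.setdiff1d(np.arange(m), A)
    residual = float(np.clip(f_net[np.ix_(A, notA)], 0.0, None).sum())
    return paths, residual


def analyze(model: TransitionModel, A, B, max_paths: int = 100) -> TPTResult:
    """Run the full TPT pipeline (committors, flux, rate, pathways) on a model."""
    A, B = _check_sets(model.m, A, B)
    q_plus = committor(model, A, B)
    q_minus = backward_committor(model, A, B)
    f, f_net, F = reactive_flux(model, q_plus, q_minus, A=A)
    if F > 0:
        k = rate(F, model, q_plus)
        paths, residual = shortest_pathways(f_net, A, B, max_paths=max_paths)
    else:
        k, paths, residual = 0.0, [], 0.0
    return TPTResult(tuple(A.tolist()), tuple(B.tolist()), q_plus, q_minus,
                     f, f_net, float(F), float(k), paths, residual)


# ---------------------------------------------------------------------------
# simulation oracle
# ---------------------------------------------------------------------------

def simulate_rate_oracle(
    model: TransitionModel | np.ndarray,
    A,
    B,
    n_steps: int = 10**6,
    seed: int = 0,
) -> dict:
    """Empirical A→B rate and mean first-passage time by chain simulation.

    Simulates ``n_steps`` of the chain, labels every step by the core set (A
    or B) visited most recently, counts completed A→B reactive events, and
    reports ``k_AB = events / (steps last-in-A)`` per τ — the event rate among
    the non-committed stationary mass, i.e. the quantity the TPT rate
    expression estimates.  Also reports the mean first-passage time to B
    averaged over all visits to A.
    """
    T = model.T if isinstance(model, TransitionModel) else np.asarray(model, float)
    tau = model.lag if isinstance(model, TransitionModel) else 1.0
    A, B = _check_sets(T.shape[0], A, B)
    seq = generate_markov_chain(T, n_steps, start="stationary", seed=seed)
    s = seq.labels
    inA = np.isin(s, A)
    inB = np.isin(s, B)
    core = np.where(inA, 0, np.where(inB, 1, -1))
    # forward-fill the last visited core set
    idx = np.where(core >= 0, np.arange(n_steps), -1)
    np.maximum.accumulate(idx, out=idx)
    started = idx >= 0
    last = np.where(started, core[np.clip(idx, 0, None)], -1)
    events = int(np.sum((last[1:] == 1) & (last[:-1] == 0)))
    steps_in_A = int(np.sum(last[:-1] == 0))
    if steps_in_A == 0:
        raise DataError("chain never visited A")
    k_emp = events / (steps_in_A * tau)
    # mean first-passage time to B over all frames in A
    ar = np.arange(n_steps, dtype=np.int64)
    marker = np.where(inB, ar, np.int64(2 * n_steps))
    next_b = np.minimum.accumulate(marker[::-1])[::-1]
    next_b = np.where(next_b < 2 * n_steps, next_b, -1)
    valid = inA & (next_b >= 0)
    if valid.any():
        mfpt = float(np.mean(next_b[valid] - np.arange(n_steps)[valid])) * tau
    else:
        mfpt = np.inf
    if events == 0:
        import warnings

        warnings.warn(
            f"no completed A->B events in {n_steps} steps; "
            f"rate < {1.0 / (steps_in_A * tau):.3g} (lower-bound estimate)"
        )
    se = np.sqrt(max(events, 1)) / (steps_in_A * tau)
    return {
        "k_AB": k_emp,
        "events": events,
        "steps_in_A": steps_in_A,
        "se": float(se),
        "mfpt_AB": mfpt,
    }
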