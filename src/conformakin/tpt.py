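"""Transition path theory on an estimated Markov state model.

Given disjoint source (A) and sink (B) state sets, the forward committor
q⁺ solves the boundary-value problem (T q)_i = q_i for i ∉ A ∪ B with
q = 0 on A and q = 1 on B; the backward committor comes from the
time-reversed chain (q⁻ = 1 − q⁺ for reversible models).  The reactive
gross flux is f_ij = π_i q⁻_i T_ij q⁺_j, netted edge-wise; pathways are
decomposed by iterative widest-path (max–min bottleneck) subtraction, and
flux fractions through intermediate state sets are read off the
decomposed pathways.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["TPTResult", "committors", "reactive_flux", "top_pathways",
           "flux_fraction_through", "transition_path_analysis"]


def _validate_sets(n: int, A, B):
    A = np.unique(np.asarray(A, dtype=np.int64))
    B = np.unique(np.asarray(B, dtype=np.int64))
    if len(A) == 0 or len(B) == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink sets must be disjoint")
    for s in (A, B):
        if s.min() < 0 or s.max() >= n:
            raise ValueError("state set outside the active set")
    return A, B


def committors(results, A, B) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committors between state sets A and B.

    ``results`` is an :class:`~conformakin.msm.MSMResults` (or any object
    with ``T`` and ``pi``).  The backward committor is computed from the
    time-reversed chain T̃_ij = π_j T_ji / π_i, which reduces to 1 − q⁺
    when detailed balance holds.
    """
    T, pi = np.asarray(results.T), np.asarray(results.pi)
    n = T.shape[0]
    A, B = _validate_sets(n, A, B)

    def _solve(Tm, src, snk):
        q = np.zeros(n)
        q[snk] = 1.0
        interior = np.setdiff1d(np.arange(n), np.concatenate([src, snk]))
        if len(interior):
            M = np.eye(len(interior)) - Tm[np.ix_(interior, interior)]
            rhs = Tm[np.ix_(interior, snk)].sum(axis=1)
            try:
                q[interior] = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"committor system singular (sink unreachable?): {err}")
        return np.clip(q, 0.0, 1.0)

    q_plus = _solve(T, A, B)
    T_rev = (pi[None, :] * T.T) / pi[:, None]
    q_minus = _solve(T_rev, B, A)
    return q_plus, q_minus


def reactive_flux(results, q_plus: np.ndarray, q_minus: np.ndarray,
                  A=None) -> tuple[np.ndarray, float]:
    """Net reactive flux matrix and total A→B flux (probability per lag).

    Gross flux f_ij = π_i q⁻_i T_ij q⁺_j for i ≠ j; the net flux is
    max(f_ij − f_ji, 0).  The total flux is the net flux out of A (which
    conservation makes equal to the net flux into B).
    """
    T, pi = np.asarray(results.T), np.asarray(results.pi)
    f = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.maximum(f - f.T, 0.0)
    if A is None:
        A = np.nonzero(q_plus == 0.0)[0]
    A = np.asarray(A, dtype=np.int64)
    not_A = np.setdiff1d(np.arange(T.shape[0]), A)
    total = float(net[np.ix_(A, not_A)].sum())
    return net, total


def _widest_path(flux: np.ndarray, A, B):
    """Widest (max–min-capacity) A→B path; lexicographic tie-break.

    Dijkstra-style search maximising the path bottleneck; among equal
    bottlenecks the lexicographically smallest state sequence wins, so
    the decomposition is deterministic.  Returns (path, bottleneck) or
    (None, 0.0).
    """
    n = flux.shape[0]
    width = np.full(n, -1.0)
    best_path = {}
    heap = []
    for a in sorted(A):
        width[a] = np.inf
        best_path[a] = (a,)
        heapq.heappush(heap, (-np.inf, (a,)))
    Bset = set(int(b) for b in B)
    visited = np.zeros(n, dtype=bool)
    while heap:
        negw, path = heapq.heappop(heap)
        u = path[-1]
        if visited[u] or path != best_path.get(u):
            continue
        visited[u] = True
        if u in Bset:
            return list(path), -negw
        for v in np.nonzero(flux[u] > 0)[0]:
            v = int(v)
            if visited[v]:
                continue
            w = min(-negw, flux[u, v])
            cand = path + (v,)
            if w > width[v] or (w == width[v] and cand < best_path.get(v, cand + (n,))):
                width[v] = w
                best_path[v] = cand
                heapq.heappush(heap, (-w, cand))
    return None, 0.0


def top_pathways(net_flux: np.ndarray, A, B, total_flux: float | None = None,
                 stop_fraction: float = 0.9, max_paths: int = 1000) -> list:
    """Pathway decomposition by iterative bottleneck subtraction.

    Repeatedly finds the widest A→B path through the remaining net flux,
    records it with its bottleneck flux, subtracts that flux along the
    path, and stops once the recorded flux reaches ``stop_fraction`` of
    the total (or no path remains).  Returns (path, flux) pairs in
    decreasing flux order.
    """
    flux = np.array(net_flux, dtype=float)
    A, B = _validate_sets(flux.shape[0], A, B)
    if total_flux is None:
        not_A = np.setdiff1d(np.arange(flux.shape[0]), A)
        total_flux = float(flux[np.ix_(A, not_A)].sum())
    if total_flux <= 0:
        warnings.warn("total flux is zero; no pathways")
        return []
    paths = []
    recorded = 0.0
    for _ in range(max_paths):
        path, width = _widest_path(flux, A, B)
        if path is None or width <= 0:
            break
        paths.append((path, width))
        for u, v in zip(path[:-1], path[1:]):
            flux[u, v] -= width
        recorded += width
        if recorded >= stop_fraction * total_flux - 1e-15:
            break
    return paths


def flux_fraction_through(pathways: list, intermediate_set, A=None, B=None) -> float:
    """Fraction of decomposed pathway flux visiting an intermediate state set.

    The fraction is (flux of pathways containing at least one state of
    the set) / (total decomposed flux).  The set must not intersect the
    source or sink sets.
    """
    inter = set(int(s) for s in np.atleast_1d(np.asarray(intermediate_set, dtype=np.int64)))
    for name, s in (("source", A), ("sink", B)):
        if s is not None and inter & set(int(x) for x in np.atleast_1d(s)):
            raise ValueError(f"intermediate set intersects the {name} set")
    total = sum(f for _, f in pathways)
    if total == 0:
        return 0.0
    hit = sum(f for path, f in pathways if inter & set(path))
    return hit / total


@dataclass
class TPTResult:
    """Committors, net reactive flux and decomposed pathways for one A→B pair."""

    source_set: np.ndarray
    sink_set: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    pathways: list = field(default_factory=list)

    def flux_fraction_through(self, intermediate_set) -> float:
        return flux_fraction_through(self.pathways, intermediate_set,
                                     A=self.source_set, B=self.sink_set)

    def rate(self, lag_time: float) -> float:
        """Reactive flux per unit time (total_flux / τ)."""
        return self.total_flux / lag_time

    def summary(self) -> str:
        lines = [
            "Transition path theory",
            "=" * 44,
            f"source/sink sizes:  {len(self.source_set)} / {len(self.sink_set)}",
            f"total flux:         {self.total_flux:.6g} per lag",
            f"pathways recorded:  {len(self.pathways)}",
        ]
        for path, f in self.pathways[:5]:
            lines.append(f"  {'->'.join(map(str, path))}   flux {f:.4g} "
                         f"({100 * f / self.total_flux:.1f}%)")
        return "\n".join(lines)


def transition_path_analysis(results, A, B, stop_fraction: float = 0.9) -> TPTResult:
    """Full TPT workflow: committors → net flux → pathway decomposition."""
    q_plus, q_minus = committors(results, A, B)
    A_, B_ = _validate_sets(results.T.shape[0], A, B)
    net, total = reactive_flux(results, q_plus, q_minus, A=A_)
    paths = top_pathways(net, A_, B_, total_flux=total, stop_fraction=stop_fraction)
    return TPTResult(source_set=A_, sink_set=B_, q_plus=q_plus, q_minus=q_minus,
                     net_flux=net, total_flux=total, pathways=paths)
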