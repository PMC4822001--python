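"""Discretization of the projected phase space.

Microstates come from greedy farthest-point k-centers in tIC space (a
2-approximation to the optimal covering radius); coarse interface-topology
macrostates come from agglomerative hierarchical clustering on a pairwise
subset-RMSD matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.cluster.hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = ["KCentersResult", "k_centers", "assign_to_centers",
           "MacrostateModel", "hierarchical_macrostates"]


@dataclass
class KCentersResult:
    centers: np.ndarray              # (k, dim) center coordinates
    center_indices: np.ndarray       # (k,) indices into the pooled point set
    assignments: np.ndarray          # per-point nearest-center index (pooled)
    distances: np.ndarray            # per-point distance to its center
    dtrajs: list                     # per-source discrete trajectories

    @property
    def n_states(self) -> int:
        return len(self.center_indices)

    @property
    def covering_radius(self) -> float:
        return float(self.distances.max())


def k_centers(points, k: int, seed: Optional[int] = None) -> KCentersResult:
    """Greedy farthest-point k-centers clustering (Euclidean metric).

    ``points`` is one (n, dim) array or a list of them (one per source
    trajectory).  The first center is point 0 by default; passing a seed
    draws the first center uniformly instead.  Every subsequent center is
    the point farthest from its nearest existing center, so the covering
    radius is within 2× optimal.  Deterministic given the seed.
    """
    if isinstance(points, np.ndarray):
        arrays = [np.atleast_2d(np.asarray(points, dtype=float))]
    else:
        arrays = [np.atleast_2d(np.asarray(p, dtype=float)) for p in points]
    pooled = np.vstack(arrays)
    n = pooled.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of frames {n}")

    if seed is None:
        first = 0
    else:
        first = int(np.random.default_rng(seed).integers(n))

    center_idx = np.empty(k, dtype=np.int64)
    center_idx[0] = first
    dist = np.linalg.norm(pooled - pooled[first], axis=1)
    assign = np.zeros(n, dtype=np.int64)
    for c in range(1, k):
        far = int(np.argmax(dist))
        if dist[far] == 0.0:
            logger.warning("k_centers: duplicate points reduce effective k to %d", c)
        center_idx[c] = far
        d_new = np.linalg.norm(pooled - pooled[far], axis=1)
        closer = d_new < dist
        dist[closer] = d_new[closer]
        assign[closer] = c

    dtrajs, off = [], 0
    for a in arrays:
        dtrajs.append(assign[off:off + a.shape[0]].copy())
        off += a.shape[0]
    return KCentersResult(centers=pooled[center_idx], center_indices=center_idx,
                          assignments=assign, distances=dist, dtrajs=dtrajs)


def assign_to_centers(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment of new points (Euclidean)."""
    from scipy.spatial.distance import cdist

    p = np.atleast_2d(np.asarray(points, dtype=float))
    return np.argmin(cdist(p, np.atleast_2d(centers)), axis=1)


@dataclass
class MacrostateModel:
    """Coarse interface-topology states from hierarchical clustering on RMSD."""

    n_macrostates: int
    assignments: np.ndarray          # per-frame macrostate label in [0, n)
    populations: np.ndarray          # frame fraction per macrostate
    representative_frames: np.ndarray  # frame index minimising mean RMSD to its cluster

    def __post_init__(self) -> None:
        if abs(self.populations.sum() - 1.0) > 1e-12:
            raise ValueError("macrostate populations must sum to 1")
        if np.any(np.bincount(self.assignments, minlength=self.n_macrostates) == 0):
            raise ValueError("every macrostate must be non-empty")


def hierarchical_macrostates(rmsd_matrix: np.ndarray, n_macrostates: int = 5,
                             linkage: str = "average") -> MacrostateModel:
    """Agglomerative clustering of frames into macrostates on a pairwise RMSD matrix.

    Average linkage by default (complete also supported); the tree is cut
    at ``n_macrostates``.  Populations are frame fractions; each
    macrostate's representative is the frame with minimal mean RMSD to the
    other members.  Labels are renumbered by first occurrence so the
    partition is deterministic.
    """
    m = np.asarray(rmsd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("rmsd_matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("rmsd_matrix must be symmetric")
    if np.any(np.abs(np.diag(m)) > 1e-8):
        raise ValueError("rmsd_matrix must have a zero diagonal")
    n = m.shape[0]
    if n_macrostates > n:
        raise ValueError("more macrostates than frames")

    msym = 0.5 * (m + m.T)
    np.fill_diagonal(msym, 0.0)
    if n_macrostates == n:
        labels = np.arange(n)
    else:
        z = scipy.cluster.hierarchy.linkage(squareform(msym, checks=False),
                                            method=linkage)
        labels = scipy.cluster.hierarchy.fcluster(z, t=n_macrostates,
                                                  criterion="maxclust") - 1
    # renumber by first occurrence
    remap, nxt = {}, 0
    out = np.empty(n, dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]

    pops = np.bincount(out, minlength=nxt) / n
    reps = np.empty(nxt, dtype=np.int64)
    for c in range(nxt):
        members = np.nonzero(out == c)[0]
        mean_rmsd = msym[np.ix_(members, members)].mean(axis=1)
        reps[c] = members[int(np.argmin(mean_rmsd))]
    return MacrostateModel(n_macrostates=nxt, assignments=out,
                           populations=pops, representative_frames=reps)
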