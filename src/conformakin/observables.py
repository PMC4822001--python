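"""Experiment-facing observables from weighted conformational ensembles.

NMR generalized order parameters S² measure the orientational restriction
of a bond vector over the ensemble (1 = rigid, 0 = isotropic); torsion
mutual information measures dynamical coupling between rotameric degrees
of freedom and, aggregated to residue pairs, maps allosteric
communication.  Both accept per-frame probability weights so MSM
equilibrium ensembles (weight = π(state)/frames-in-state) and plain
trajectory ensembles share one code path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["order_parameters_s2", "s2_from_vectors", "msm_frame_weights",
           "torsion_mutual_information", "MIMatrix", "mutual_information_matrix",
           "aggregate_residue_coupling", "correlate_with_experiment"]


def _check_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights length must match number of frames")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    return w


def msm_frame_weights(results, assignments) -> np.ndarray:
    """Equilibrium frame weights from an MSM: w(frame) = π(state)/n_frames(state)."""
    assign = np.asarray(assignments, dtype=np.int64)
    counts = np.bincount(assign, minlength=results.n_states)
    if np.any(counts[: results.n_states] == 0):
        missing = int(np.nonzero(counts == 0)[0][0])
        raise ValueError(f"state {missing} has no frames")
    w = results.pi[assign] / counts[assign]
    return w / w.sum()


def s2_from_vectors(vectors: np.ndarray, weights=None) -> float:
    """Generalized order parameter of one bond-vector ensemble.

    S² = (3 [⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²] − 1) / 2

    with ⟨·⟩ the weighted ensemble average of products of the unit-vector
    Cartesian components (the isotropic-ensemble second-rank formula).
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vectors must have shape (n_frames, 3)")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vectors are not orientations")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("vectors must be unit-norm (within 1e-6)")
    w = _check_weights(weights, v.shape[0])
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    mom = (np.dot(w, x * x) ** 2 + np.dot(w, y * y) ** 2 + np.dot(w, z * z) ** 2
           + 2 * np.dot(w, x * y) ** 2 + 2 * np.dot(w, x * z) ** 2
           + 2 * np.dot(w, y * z) ** 2)
    return 0.5 * (3.0 * mom - 1.0)


def order_parameters_s2(vectors_by_residue: dict, weights=None,
                        vector_type: str = "backbone_NH") -> dict:
    """S² per residue from per-frame unit bond vectors.

    ``vectors_by_residue`` maps residue index → (n_frames, 3) unit
    vectors (e.g. backbone N–H directions); one weight vector applies to
    all residues.  Returns residue → S² in [0, 1].
    """
    out = {}
    for resid, v in vectors_by_residue.items():
        s2 = s2_from_vectors(v, weights)
        if not -1e-9 <= s2 <= 1.0 + 1e-9:
            raise ValueError(f"S² {s2} out of range for residue {resid}")
        out[int(resid)] = float(min(max(s2, 0.0), 1.0))
    return out


def _bin_edges(x: np.ndarray, bins: int, binning: str) -> np.ndarray:
    if binning == "fixed":
        return np.linspace(-np.pi, np.pi, bins + 1)
    if binning == "quantile":
        edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, bins + 1)))
        if len(edges) < 2:  # constant series: a single degenerate bin
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
        edges[0] -= 1e-12
        edges[-1] += 1e-12
        return edges
    raise ValueError(f"binning must be 'quantile' or 'fixed', got {binning!r}")


def torsion_mutual_information(angles_a, angles_b, weights=None, bins: int = 24,
                               correction: str = "shuffle_null",
                               binning: str = "quantile",
                               n_shuffles: int = 20, seed: int = 42) -> float:
    """Mutual information (nats) between two torsion series.

    Histogram estimator on a bins×bins grid.  ``binning="quantile"``
    (default) places edges at equal-occupancy quantiles of each marginal —
    the adaptive partitioning torsion-MI methods use, which keeps the
    discretization bias small for sharply peaked rotamer distributions;
    ``binning="fixed"`` uses equal-width bins on (−π, π].  With
    ``correction="shuffle_null"`` the mean MI of ``n_shuffles`` independent
    permutations of one series is subtracted and the result floored at 0,
    removing the positive finite-sample bias.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    n = len(a)
    if n < bins * bins / 10:
        logger.warning("only %d frames for %d^2 bins: MI likely undersampled", n, bins)
    w = _check_weights(weights, n)
    ea = _bin_edges(a, bins, binning)
    eb = _bin_edges(b, bins, binning)

    def _mi(x, y):
        h, _, _ = np.histogram2d(x, y, bins=[ea, eb], weights=w)
        p = h / h.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        nz = p > 0
        return float((p[nz] * np.log(p[nz] / (px[:, None] * py[None, :])[nz])).sum())

    mi = _mi(a, b)
    if correction == "none":
        return mi
    if correction != "shuffle_null":
        raise ValueError(f"unknown correction {correction!r}")
    rng = np.random.default_rng(seed)
    null = np.mean([_mi(a, rng.permutation(b)) for _ in range(n_shuffles)])
    return max(mi - null, 0.0)


@dataclass
class MIMatrix:
    """Pairwise torsion mutual information (nats)."""

    values: np.ndarray
    labels: list
    bins: int
    correction: str

    def __post_init__(self) -> None:
        if not np.allclose(self.values, self.values.T):
            raise ValueError("MI matrix must be symmetric")


def mutual_information_matrix(angles: np.ndarray, labels=None, weights=None,
                              bins: int = 24, correction: str = "shuffle_null",
                              seed: int = 42) -> MIMatrix:
    """All-pairs torsion MI for an (n_frames, n_torsions) angle array."""
    a = np.asarray(angles, dtype=float)
    k = a.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = torsion_mutual_information(
                a[:, i], a[:, j], weights=weights, bins=bins,
                correction=correction, seed=seed)
    if labels is None:
        labels = list(range(k))
    return MIMatrix(values=out, labels=list(labels), bins=bins, correction=correction)


def aggregate_residue_coupling(mi: MIMatrix, mapping, mode: str = "max"):
    """Aggregate a torsion-level MI matrix to residue-pair coupling.

    ``mapping`` maps each torsion label to its residue; the residue-pair
    value is the max (default) or sum of MI over their torsion pairs.
    Returns ``(residues, matrix)``.
    """
    try:
        resids = [mapping[lab] for lab in mi.labels]
    except KeyError as err:
        raise ValueError(f"torsion {err.args[0]!r} missing from mapping")
    residues = sorted(set(resids))
    idx = {r: i for i, r in enumerate(residues)}
    if mode not in ("max", "sum"):
        raise ValueError(f"mode must be 'max' or 'sum', got {mode!r}")
    out = np.zeros((len(residues), len(residues)))
    k = len(mi.labels)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = idx[resids[i]], idx[resids[j]]
            v = mi.values[i, j]
            if mode == "max":
                out[a, b] = out[b, a] = max(out[a, b], v)
            else:
                out[a, b] += v
                if a != b:
                    out[b, a] += v
    return residues, out


def correlate_with_experiment(computed: dict, experimental: dict):
    """Pearson correlation of computed vs experimental per-residue values.

    Returns ``(r, residuals, missing)`` where residuals maps overlapping
    residues to computed − experimental and missing lists residues absent
    on either side.  Requires at least 3 overlapping residues.
    """
    from scipy.stats import pearsonr

    common = sorted(set(computed) & set(experimental))
    missing = sorted((set(computed) ^ set(experimental)))
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping residues; need >= 3")
    c = np.array([computed[r] for r in common], dtype=float)
    e = np.array([experimental[r] for r in common], dtype=float)
    r, _ = pearsonr(c, e)
    residuals = {res: float(cv - ev) for res, cv, ev in zip(common, c, e)}
    return float(r), residuals, missing
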