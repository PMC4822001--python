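"""Feature representations of trajectories.

The analysis represents each conformation as a vector |X⟩ of minimum
heavy-atom distances between residue pairs separated in sequence by at
least three residues (the contact map), plus named inter-residue
distances, backbone/side-chain torsion angles, least-squares subset RMSD
and the partial-unfolding classifier built on two inter-Cα distances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ContactFeatures",
    "contact_features",
    "pair_distance",
    "classify_partial_unfolding",
    "dihedral",
    "torsion_angles",
    "phi_psi_indices",
    "subset_rmsd",
]


@dataclass
class ContactFeatures:
    """Per-frame contact-map feature vectors.

    ``values`` has shape (n_frames, d); ``pair_labels`` lists the residue
    index pair (i, j), i < j, behind each of the d columns.
    """

    values: np.ndarray
    pair_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None]
        if self.values.shape[1] != len(self.pair_labels):
            raise ValueError("feature dimension does not match pair_labels")
        for i, j in self.pair_labels:
            if not i < j:
                raise ValueError(f"pair label ({i}, {j}) not strictly ordered")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def contact_features(traj: Trajectory, min_separation: int = 3) -> ContactFeatures:
    """Minimum heavy-atom distance for every residue pair with j − i ≥ min_separation.

    The separation filter is on the residue sequence indices of the
    topology.  Distances are in Å; one feature vector per frame.
    """
    top = traj.topology
    residues = top.residues
    heavy = {}
    for r in residues:
        idx = top.atoms_of_residue(int(r), heavy_only=True)
        if len(idx) == 0:
            raise ValueError(f"residue {r} has no heavy atoms")
        heavy[int(r)] = idx

    pairs = [(int(a), int(b)) for k, a in enumerate(residues)
             for b in residues[k + 1:] if b - a >= min_separation]
    xyz = traj.coordinates
    values = np.empty((traj.n_frames, len(pairs)))
    for col, (a, b) in enumerate(pairs):
        da = xyz[:, heavy[a], None, :] - xyz[:, None, heavy[b], :]
        d = np.sqrt((da ** 2).sum(-1))
        values[:, col] = d.reshape(traj.n_frames, -1).min(axis=1)
    return ContactFeatures(values, pairs)


def pair_distance(traj: Trajectory, pair, mode: str = "min_heavy") -> np.ndarray:
    """Per-frame distance (Å) between two residues.

    ``mode="min_heavy"`` takes the minimum over heavy-atom pairs
    (consistent with :func:`contact_features`); ``mode="c_alpha"`` the
    CA–CA distance.
    """
    a, b = int(pair[0]), int(pair[1])
    top = traj.topology
    xyz = traj.coordinates
    if mode == "c_alpha":
        ia = top.atom_index(a, "CA")
        ib = top.atom_index(b, "CA")
        return np.linalg.norm(xyz[:, ia] - xyz[:, ib], axis=1)
    if mode == "min_heavy":
        ias = top.atoms_of_residue(a, heavy_only=True)
        ibs = top.atoms_of_residue(b, heavy_only=True)
        if len(ias) == 0:
            raise ValueError(f"residue {a} has no heavy atoms")
        if len(ibs) == 0:
            raise ValueError(f"residue {b} has no heavy atoms")
        d = np.sqrt(((xyz[:, ias, None, :] - xyz[:, None, ibs, :]) ** 2).sum(-1))
        return d.reshape(traj.n_frames, -1).min(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def classify_partial_unfolding(d_M124_A128, d_A128_G134,
                               cutoff_1: float = 11.0, cutoff_2: float = 15.0,
                               combine: str = "or"):
    """Classify conformations as partially unfolded from two inter-Cα distances.

    A conformation counts as partially unfolded when the Met124–Ala128
    distance exceeds 11 Å (helix-G unwinding) or the Ala128–Gly134
    distance exceeds 15 Å (deformation of the second Ca²⁺-binding site).
    Either deformation alone suffices under the default ``combine="or"``;
    ``combine="and"`` requires both.  Accepts scalars or arrays.
    """
    d1 = np.asarray(d_M124_A128, dtype=float)
    d2 = np.asarray(d_A128_G134, dtype=float)
    if np.any(d1 < 0) or np.any(d2 < 0):
        raise ValueError("distances must be nonnegative")
    over1 = d1 > cutoff_1
    over2 = d2 > cutoff_2
    if combine == "or":
        out = over1 | over2
    elif combine == "and":
        out = over1 & over2
    else:
        raise ValueError(f"combine must be 'or' or 'and', got {combine!r}")
    return bool(out) if out.ndim == 0 else out


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians, IUPAC convention) about the p1–p2 bond.

    Right-handed sign; trans → ±π, cis → 0.  Accepts arrays of points with
    leading frame dimensions.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = (n1 * n2).sum(-1)
    y = (np.cross(n1, n2) * b1n).sum(-1)
    return np.arctan2(y, x)


def phi_psi_indices(traj: Trajectory):
    """Atom-index quadruples for backbone φ and ψ torsions.

    Returns ``(labels, quads)`` where each label is ``("phi"|"psi", resid)``.
    Residues missing a defining atom are skipped with a warning.
    """
    top = traj.topology
    residues = [int(r) for r in top.residues]
    labels, quads = [], []

    def _try(resid, name):
        try:
            return top.atom_index(resid, name)
        except KeyError:
            return None

    for k, r in enumerate(residues):
        prev_r = residues[k - 1] if k > 0 else None
        next_r = residues[k + 1] if k + 1 < len(residues) else None
        n, ca, c = _try(r, "N"), _try(r, "CA"), _try(r, "C")
        if prev_r is not None and prev_r == r - 1:
            c_prev = _try(prev_r, "C")
            if None not in (c_prev, n, ca, c):
                labels.append(("phi", r))
                quads.append((c_prev, n, ca, c))
            else:
                logger.warning("phi(%d) undefined: missing backbone atom", r)
        if next_r is not None and next_r == r + 1:
            n_next = _try(next_r, "N")
            if None not in (n, ca, c, n_next):
                labels.append(("psi", r))
                quads.append((n, ca, c, n_next))
            else:
                logger.warning("psi(%d) undefined: missing backbone atom", r)
    return labels, quads


def torsion_angles(traj: Trajectory, selection) -> np.ndarray:
    """Per-frame torsion series for a list of atom-index quadruples.

    ``selection`` is a sequence of 4-tuples of atom indices (use
    :func:`phi_psi_indices` for standard backbone torsions).  Output shape
    is (n_frames, n_torsions), radians in (−π, π].
    """
    xyz = traj.coordinates
    out = np.empty((traj.n_frames, len(selection)))
    for k, (i, j, l, m) in enumerate(selection):
        out[:, k] = dihedral(xyz[:, i], xyz[:, j], xyz[:, l], xyz[:, m])
    return out


def subset_rmsd(frame_a: np.ndarray, frame_b: np.ndarray, atom_indices=None) -> float:
    """Optimal-superposition RMSD (Å) between two frames over an atom subset.

    Least-squares rotation + translation (Kabsch) with the proper-rotation
    (det = +1) constraint, via scipy's align_vectors.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if atom_indices is not None:
        a = a[np.asarray(atom_indices, dtype=int)]
        b = b[np.asarray(atom_indices, dtype=int)]
    if a.shape != b.shape:
        raise ValueError(f"atom subsets differ in shape: {a.shape} vs {b.shape}")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / math.sqrt(a.shape[0]))
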