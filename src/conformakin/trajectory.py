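"""Lightweight trajectory and topology containers.

Coordinates are stored in Ångström as a ``(n_frames, n_atoms, 3)`` float
array together with a flat per-atom topology (residue index, residue name,
atom name, element).  PDB files are read through :mod:`mdtraj`, converting
from its nm convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "Trajectory", "load_pdb"]


@dataclass
class Topology:
    """Flat per-atom annotation of a molecular system.

    Residue numbering follows the convention of the source structure
    (1-based for proteins, e.g. E82–A147 for the calmodulin C-lobe).
    """

    atom_names: np.ndarray          # (n_atoms,) str
    elements: np.ndarray            # (n_atoms,) str, e.g. "C", "N", "H"
    residue_ids: np.ndarray         # (n_atoms,) int, sequence index of parent residue
    residue_names: np.ndarray       # (n_atoms,) str

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.residue_ids) == len(self.residue_names) == n):
            raise ValueError("topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residues(self) -> np.ndarray:
        """Sorted unique residue sequence indices."""
        return np.unique(self.residue_ids)

    def heavy_atom_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements], dtype=bool)

    def atoms_of_residue(self, resid: int, heavy_only: bool = False) -> np.ndarray:
        mask = self.residue_ids == resid
        if heavy_only:
            mask &= self.heavy_atom_mask()
        return np.nonzero(mask)[0]

    def atom_index(self, resid: int, atom_name: str) -> int:
        idx = np.nonzero((self.residue_ids == resid) & (self.atom_names == atom_name))[0]
        if len(idx) == 0:
            raise KeyError(f"residue {resid} has no atom named {atom_name!r}")
        return int(idx[0])


@dataclass
class Trajectory:
    """A time series of conformations.

    Parameters
    ----------
    coordinates : (n_frames, n_atoms, 3) array, Å
    topology : Topology
    frame_spacing : float
        Time between recorded frames in ns (default 0.1 ns, i.e. one
        snapshot every 100 ps).
    """

    coordinates: np.ndarray
    topology: Topology
    frame_spacing: float = 0.1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def slice_frames(self, frames) -> "Trajectory":
        return Trajectory(self.coordinates[frames], self.topology, self.frame_spacing)


def _topology_from_mdtraj(top) -> Topology:
    names, elements, resids, resnames = [], [], [], []
    for atom in top.atoms:
        names.append(atom.name)
        elements.append(atom.element.symbol if atom.element is not None else "X")
        resids.append(atom.residue.resSeq)
        resnames.append(atom.residue.name)
    return Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                    np.array(resids, dtype=int), np.array(resnames, dtype=object))


def load_pdb(path, frame_spacing: float = 0.1, model: int = 0) -> Trajectory:
    """Read a PDB file into a :class:`Trajectory` (coordinates in Å).

    Multi-model (NMR-style) files yield one frame per model; ``model``
    selects a single frame, or pass ``model=None`` to keep all.
    """
    import mdtraj

    t = mdtraj.load_pdb(str(path), standard_names=False)
    coords = np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Å
    if model is not None:
        coords = coords[model:model + 1]
    return Trajectory(coords, _topology_from_mdtraj(t.topology), frame_spacing)
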