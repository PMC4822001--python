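"""Published-structure handling: C-lobe extraction and tIC projection.

The calmodulin C-lobe spans residues E82–A147.  Experimental complex
structures (PDB) are reduced to that block from a single chain, validated
for completeness, featurized with the same contact-map definition as the
trajectory data and projected into a fitted tIC space — placing the
conformations stabilised by binding partners on the free-energy landscape
of the unliganded protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import contact_features
from .trajectory import Topology, Trajectory

logger = logging.getLogger(__name__)

CLOBE_FIRST = 82
CLOBE_LAST = 147

__all__ = ["StructureRecord", "extract_clobe", "project_structures",
           "CLOBE_FIRST", "CLOBE_LAST"]


@dataclass
class StructureRecord:
    """One chain's C-lobe block extracted from a structure file."""

    pdb_id: str
    chain: str
    trajectory: Trajectory        # single frame, residues first..last only
    completeness: float           # fraction of expected residues present
    missing_residues: list

    def __post_init__(self) -> None:
        if self.completeness > 1.0 + 1e-12:
            raise ValueError("completeness cannot exceed 1")


def extract_clobe(pdb_file, chain: str, first_res: int = CLOBE_FIRST,
                  last_res: int = CLOBE_LAST, model: int = 0,
                  min_completeness: float = 0.8) -> StructureRecord:
    """Extract residues ``first_res``–``last_res`` of one chain from a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer;
    multi-model (NMR) files use the first model unless ``model`` selects
    another.  Files missing more than 20% of the expected residues are
    refused: supply a completed model rather than having coordinates
    guessed here.
    """
    import gemmi

    st = gemmi.read_pdb(str(pdb_file))
    st.remove_alternative_conformations()  # keeps highest occupancy
    st.remove_hydrogens()
    if model >= len(st):
        raise ValueError(f"model {model} absent ({len(st)} models in file)")
    mod = st[model]
    chains = [ch.name for ch in mod]
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available: {chains}")
    ch = mod[chain]

    names, elements, resids, resnames, coords = [], [], [], [], []
    present = set()
    for res in ch:
        seqid = res.seqid.num
        if not first_res <= seqid <= last_res:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        present.add(seqid)
        for atom in res:
            names.append(atom.name)
            elements.append(atom.element.name)
            resids.append(seqid)
            resnames.append(res.name)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    expected = set(range(first_res, last_res + 1))
    missing = sorted(expected - present)
    completeness = len(present) / len(expected)
    if completeness < min_completeness:
        raise ValueError(
            f"chain {chain} covers only {len(present)}/{len(expected)} residues "
            f"({completeness:.1%}) of {first_res}-{last_res}; missing {missing}. "
            "Supply a completed model (e.g. from loop modelling) instead.")
    if missing:
        logger.info("chain %s missing residues %s", chain, missing)
    top = Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                   np.array(resids, dtype=int), np.array(resnames, dtype=object))
    traj = Trajectory(np.asarray(coords, dtype=float)[None], top)
    pdb_id = (st.name or "").strip()[:4].upper() or "XXXX"
    return StructureRecord(pdb_id=pdb_id, chain=chain, trajectory=traj,
                           completeness=completeness, missing_residues=missing)


def project_structures(tica_results, records, min_separation: int = 3,
                       n: Optional[int] = None) -> np.ndarray:
    """Project structure records into a fitted tIC space.

    Each record is featurized with the same contact-map definition the
    model was trained on (its ``pair_labels``); a residue-pair mismatch
    raises rather than silently reordering features.  Returns
    (n_records, n_components) tIC coordinates.
    """
    if tica_results.pair_labels is None:
        raise ValueError("tICA model carries no pair labels; cannot align features")
    expected = [tuple(p) for p in tica_results.pair_labels]
    rows = []
    for rec in records:
        feats = contact_features(rec.trajectory, min_separation=min_separation)
        got = [tuple(p) for p in feats.pair_labels]
        if got != expected:
            missing = [p for p in expected if p not in got]
            extra = [p for p in got if p not in expected]
            bad = (missing or extra or expected)[0]
            raise ValueError(
                f"structure {rec.pdb_id}/{rec.chain}: residue pair {bad} does not "
                "match the model's contact map (incomplete or renumbered residues?)")
        rows.append(tica_results.project(feats.values[0], n=n))
    return np.asarray(rows)
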