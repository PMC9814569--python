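"""Snapshot and trajectory output: multi-model PDB, XYZ, kinetics CSV.

Bead naming: atom name is the bead type (N, CA, C for the backbone
spheres, CB for the sidechain sphere), the residue is the peptide
residue, and each peptide chain gets its own segment/chain identifier
(cycling A-Z, a-z, 0-9).
"""

from __future__ import annotations

import string
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .forcefield import KIND_CA, KIND_CO, KIND_NH, KIND_R, SystemTopology

__all__ = ["write_pdb", "write_xyz", "write_kinetics_csv", "write_cluster_report"]

_ATOM_NAMES = {KIND_NH: "N", KIND_CA: "CA", KIND_CO: "C", KIND_R: "CB"}
_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "O": "ORN", "P": "PRO", "Q": "GLN",
    "R": "ARG", "S": "SER", "T": "THR", "V": "VAL", "W": "TRP",
    "Y": "TYR",
}


def _universe(topology: SystemTopology, box_side: float):
    import MDAnalysis as mda

    n = topology.n_beads
    n_res = sum(len(c) for c in topology.chains)
    resindex = np.zeros(n, dtype=int)
    offset_beads = 0
    offset_res = 0
    resnames = []
    segids = []
    for c, pep in enumerate(topology.chains):
        L = len(pep)
        for r, res in enumerate(pep.residues):
            resnames.append(_ONE_TO_THREE.get(res.code, "UNK"))
            resindex[offset_beads + 4 * r : offset_beads + 4 * r + 4] = (
                offset_res + r
            )
        segids.append(_CHAIN_IDS[c % len(_CHAIN_IDS)])
        offset_beads += 4 * L
        offset_res += L

    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        n_segments=len(topology.chains),
        atom_resindex=resindex,
        residue_segindex=np.repeat(
            np.arange(len(topology.chains)),
            [len(c) for c in topology.chains],
        ),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [
        _ATOM_NAMES[int(k)] for k in topology.bead_kind
    ])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.concatenate(
        [np.arange(1, len(c) + 1) for c in topology.chains]
    ))
    u.add_TopologyAttr("chainIDs", [
        _CHAIN_IDS[int(c) % len(_CHAIN_IDS)] for c in topology.chain_id
    ])
    u.add_TopologyAttr("segids", segids)
    u.dimensions = [box_side, box_side, box_side, 90.0, 90.0, 90.0]
    return u


def write_pdb(
    path: str | Path,
    topology: SystemTopology,
    positions: np.ndarray,
    box_side: float,
) -> None:
    """Write one snapshot or a (S, N, 3) stack as (multi-model) PDB."""
    import MDAnalysis as mda

    u = _universe(topology, box_side)
    frames = positions if positions.ndim == 3 else positions[None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_beads, multiframe=True) as w:
            for f in frames:
                u.atoms.positions = f
                w.write(u.atoms)


def write_xyz(
    path: str | Path,
    topology: SystemTopology,
    positions: np.ndarray,
    box_side: float,
) -> None:
    """Write snapshot(s) in XYZ format (bead names as element column)."""
    import MDAnalysis as mda

    u = _universe(topology, box_side)
    frames = positions if positions.ndim == 3 else positions[None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_beads) as w:
            for f in frames:
                u.atoms.positions = f
                w.write(u.atoms)


def write_kinetics_csv(path: str | Path, kinetics) -> None:
    """Tidy CSV: time, n_free, n_oligomer_peptides, n_fibril_peptides, n_hbonds."""
    kinetics.to_frame().to_csv(path, index=False)


def write_cluster_report(
    path: str | Path,
    free: set[int],
    oligomers: Sequence[set[int]],
    fibrils: Sequence[set[int]],
    graph,
) -> None:
    """Per-cluster CSV: class, size, members, charge composition."""
    import pandas as pd

    rows = []
    for kind, clusters in (
        ("free", [{c} for c in sorted(free)]),
        ("oligomer", oligomers),
        ("fibril", fibrils),
    ):
        for members in clusters:
            charges = [graph.nodes[m]["charge"] for m in members]
            rows.append(
                {
                    "cluster_class": kind,
                    "size": len(members),
                    "members": ";".join(str(m) for m in sorted(members)),
                    "n_cationic": sum(1 for q in charges if q > 0),
                    "n_anionic": sum(1 for q in charges if q < 0),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
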