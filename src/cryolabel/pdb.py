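"""Biological-assembly PDB parsing and atom-class assignment.

Assemblies (``.pdb1``) may replicate one chain over several ``MODEL`` blocks;
here every model contributes atoms (assembly copies, not conformers).
Parsing is delegated to :mod:`gemmi`; alternate-location handling and water
filtering follow the conventions below.

Atom classes for the atom-type label map: Cα=1, Cβ=2, carbonyl carbon=3,
oxygen=4, nitrogen=5, everything else (side-chain carbons, S, P, metals)=0.
Classes 1–3 require a standard amino-acid residue in a non-HETATM record, so
a calcium ion (atom name "CA" in a HETATM) stays 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import gemmi
import numpy as np

from .exceptions import EmptyStructureError, InvalidParameterError

__all__ = ["Atom", "Structure", "AtomClass", "read_assembly", "classify_atom", "write_pdb"]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


class AtomClass(IntEnum):
    OTHER = 0
    CA = 1
    CB = 2
    CARBONYL_C = 3
    O = 4
    N = 5


@dataclass
class Atom:
    element: str
    name: str
    residue_name: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    alt_loc: str = ""
    model_id: int = 1
    is_hetero: bool = False
    chain_id: str = "A"
    residue_seq: int = 1

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise InvalidParameterError(f"non-finite atom coordinates {self.coords}")
        self.occupancy = float(min(1.0, max(0.0, self.occupancy)))


@dataclass
class Structure:
    """Ordered atom collection from one biological assembly."""

    atoms: list[Atom]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of (x, y, z) in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)


def read_assembly(
    path,
    include_hetero: bool = True,
    skip_waters: bool = True,
    alt_loc_policy: str = "occupancy",
) -> Structure:
    """Parse a PDB / .pdb1 file into a flat, file-ordered :class:`Structure`.

    All ``MODEL`` blocks are concatenated (assembly copies).  Waters are
    dropped when ``skip_waters``.  ``alt_loc_policy``: ``"occupancy"`` keeps
    the highest-occupancy alternate (ties: first in file), ``"first"`` keeps
    the first record, ``"all"`` keeps every alternate.
    """
    if alt_loc_policy not in ("occupancy", "first", "all"):
        raise InvalidParameterError(f"unknown alt_loc policy {alt_loc_policy!r}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    source_id = st.name or Path(path).stem

    atoms: list[Atom] = []
    best: dict[tuple, tuple[float, int]] = {}  # altloc group -> (occ, position)
    for model in st:
        model_id = int(model.num) if str(model.num).isdigit() else 1
        for chain in model:
            for residue in chain:
                resname = residue.name.strip()
                is_het = residue.het_flag == "H"
                if skip_waters and resname in WATER_RESIDUES:
                    continue
                if not include_hetero and is_het:
                    continue
                for at in residue:
                    atom = Atom(
                        element=at.element.name.upper(),
                        name=at.name.strip(),
                        residue_name=resname,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        alt_loc=at.altloc if at.altloc != "\0" else "",
                        model_id=model_id,
                        is_hetero=is_het,
                        chain_id=chain.name,
                        residue_seq=residue.seqid.num,
                    )
                    if alt_loc_policy == "all" or not atom.alt_loc:
                        atoms.append(atom)
                        continue
                    key = (model_id, chain.name, residue.seqid.num,
                           residue.seqid.icode, resname, atom.name)
                    if key not in best:
                        best[key] = (atom.occupancy, len(atoms))
                        atoms.append(atom)
                    elif alt_loc_policy == "occupancy" and atom.occupancy > best[key][0]:
                        _, pos = best[key]
                        best[key] = (atom.occupancy, pos)
                        atoms[pos] = atom  # replace in place, keep file order
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms left after filtering")
    return Structure(atoms=atoms, source_id=source_id)


def classify_atom(atom: Atom) -> AtomClass:
    """Atom-type label code for one atom (pure function of its fields)."""
    if not atom.is_hetero and atom.residue_name in STANDARD_AA:
        if atom.name == "CA":
            return AtomClass.CA
        if atom.name == "CB":
            return AtomClass.CB
        if atom.name == "C":
            return AtomClass.CARBONYL_C
    if atom.element == "O":
        return AtomClass.O
    if atom.element == "N":
        return AtomClass.N
    return AtomClass.OTHER


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: 1- or 2-letter elements align differently
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column ATOM/HETATM records, one MODEL block per model id."""
    lines: list[str] = []
    current_model = None
    serial = 0
    model_ids = {a.model_id for a in structure.atoms}
    multi = len(model_ids) > 1
    for atom in structure.atoms:
        if multi and atom.model_id != current_model:
            if current_model is not None:
                lines.append("ENDMDL")
            lines.append(f"MODEL     {atom.model_id:4d}")
            current_model = atom.model_id
        serial += 1
        record = "HETATM" if atom.is_hetero else "ATOM  "
        x, y, z = atom.coords
        lines.append(
            f"{record}{serial % 100000:5d} {_format_atom_name(atom.name, atom.element)}"
            f"{atom.alt_loc or ' ':1s}{atom.residue_name:>3s} {atom.chain_id:1s}"
            f"{atom.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
        )
    if multi:
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
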