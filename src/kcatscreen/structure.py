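"""Structure model and PDB input for the geometry screens.

A deliberately small atom-table container: fixed-column PDB files are read
through Biopython, altloc ambiguity is resolved once at load time (keep the
blank/'A' conformer, highest occupancy on a tie), and downstream geometry
code sees exactly one conformer per atom. Residues are addressed by
``(chain, author_residue_number)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int       # author numbering
    coord: tuple[float, float, float]
    element: str
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class StructureModel:
    """Atom table plus a ``(chain, resnum) -> atom indices`` residue index."""

    atoms: list[Atom]
    residue_index: dict[tuple[str, int], list[int]] = field(default_factory=dict)
    flagged_residues: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.residue_index:
            for i, a in enumerate(self.atoms):
                self.residue_index.setdefault(
                    (a.chain, a.residue_number), []).append(i)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def residues(self):
        """Iterate ``((chain, resnum), residue_name, [Atom, ...])`` in
        residue-number order."""
        for key in sorted(self.residue_index):
            atoms = [self.atoms[i] for i in self.residue_index[key]]
            yield key, atoms[0].residue_name, atoms

    def residue_atoms(self, chain: str, resnum: int) -> list[Atom]:
        return [self.atoms[i] for i in self.residue_index[(chain, resnum)]]

    def has_residue(self, chain: str, resnum: int) -> bool:
        return (chain, resnum) in self.residue_index

    def residue_name(self, chain: str, resnum: int) -> str:
        return self.atoms[self.residue_index[(chain, resnum)][0]].residue_name

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)


def _pick_altloc(candidates):
    """Altloc policy: keep blank or 'A'; break ties by occupancy (desc)."""
    preferred = [a for a in candidates if a.get_altloc() in (" ", "", "A")]
    pool = preferred or list(candidates)
    return max(pool, key=lambda a: (a.get_occupancy() or 0.0,
                                    a.get_altloc() in (" ", "")))


def read_pdb(path, chain: str | None = None,
             include_hetatm: bool = False) -> StructureModel:
    """Parse ATOM records of one chain of a PDB file.

    Waters and HETATM records are excluded by default; altlocs are
    resolved at load. ``chain=None`` selects the first chain present.
    Residues lacking a C-alpha are kept but flagged (with a warning).
    Raises if the file yields no ATOM records.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio_structure = parser.get_structure("s", str(path))
    try:
        model = next(bio_structure.get_models())
    except StopIteration:
        raise ValueError(f"no ATOM records in {path}") from None

    atoms: list[Atom] = []
    for bio_chain in model:
        if chain is not None and bio_chain.id != chain:
            continue
        if chain is None and atoms and bio_chain.id != atoms[0].chain:
            break  # first chain only
        for residue in bio_chain:
            hetflag = residue.id[0]
            if hetflag == "W":
                continue
            if hetflag != " " and not include_hetatm:
                continue
            for bio_atom in residue:
                if bio_atom.is_disordered():
                    bio_atom = _pick_altloc(bio_atom.disordered_get_list())
                x, y, z = (float(v) for v in bio_atom.coord)
                atoms.append(Atom(
                    serial=bio_atom.serial_number or 0,
                    name=bio_atom.get_name(),
                    residue_name=residue.get_resname(),
                    chain=bio_chain.id,
                    residue_number=residue.id[1],
                    coord=(x, y, z),
                    element=(bio_atom.element or "").strip() or
                            bio_atom.get_name()[:1],
                    occupancy=float(bio_atom.get_occupancy() or 1.0),
                    altloc=bio_atom.get_altloc().strip(),
                ))
    if not atoms:
        raise ValueError(f"no ATOM records in {path}"
                         + (f" for chain {chain!r}" if chain else ""))
    s = StructureModel(atoms=atoms)
    for key, resname, res_atoms in s.residues():
        if resname in THREE_TO_ONE and not any(a.name == "CA"
                                               for a in res_atoms):
            log.warning("residue %s %s has no CA; flagged", resname, key)
            s.flagged_residues.add(key)
    return s
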