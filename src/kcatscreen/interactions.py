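"""Salt-bridge and hydrogen-bond detection on heavy-atom geometry.

Crystal structures rarely resolve hydrogens, so both detectors use
heavy-atom distance criteria only: a salt bridge is a basic side-chain
nitrogen within ``cutoff`` (default 4.0 Å, the common literature
convention) of an acidic side-chain oxygen; a hydrogen bond is any
donor-capable/acceptor-capable N/O pair within ``d_cutoff`` (default
3.5 Å), excluding intra-residue pairs and covalent backbone geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import StructureModel

log = logging.getLogger(__name__)

#: Charged side-chain groups used for salt-bridge detection.
BASIC_GROUP_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class SaltBridge:
    basic: tuple[str, int]     # (chain, resnum)
    acidic: tuple[str, int]
    distance: float            # min charged-group heavy-atom distance, Å

    @property
    def residues(self) -> frozenset:
        return frozenset((self.basic, self.acidic))


@dataclass(frozen=True)
class HydrogenBond:
    donor_residue: tuple[str, int]
    donor_atom: str
    acceptor_residue: tuple[str, int]
    acceptor_atom: str
    distance: float
    donor_is_sidechain: bool
    acceptor_is_sidechain: bool

    @property
    def residues(self) -> frozenset:
        return frozenset((self.donor_residue, self.acceptor_residue))


@dataclass
class InteractionInventory:
    """Deduplicated salt bridges and hydrogen bonds of one structure."""

    salt_bridges: list[SaltBridge] = field(default_factory=list)
    hbonds: list[HydrogenBond] = field(default_factory=list)

    def bridges_of(self, residue: tuple[str, int]) -> list[SaltBridge]:
        return [b for b in self.salt_bridges if residue in b.residues]

    def sidechain_hbonds_of(self, residue: tuple[str, int]) -> list[HydrogenBond]:
        out = []
        for hb in self.hbonds:
            if hb.donor_residue == residue and hb.donor_is_sidechain:
                out.append(hb)
            elif hb.acceptor_residue == residue and hb.acceptor_is_sidechain:
                out.append(hb)
        return out


def detect_salt_bridges(s: StructureModel,
                        cutoff: float = 4.0,
                        include_his: bool = True) -> list[SaltBridge]:
    """All basic/acidic residue pairs whose charged-group heavy atoms come
    within ``cutoff`` Å; each pair reported once with its minimum distance.

    Residues missing their charged side-chain atoms are skipped with a
    log message (truncated side chains are common in crystal structures).
    """
    basic_names = dict(BASIC_GROUP_ATOMS)
    if not include_his:
        basic_names.pop("HIS")

    def group_atoms(table):
        out = []  # (residue key, coords array)
        for key, resname, atoms in s.residues():
            if resname not in table:
                continue
            coords = [a.coord for a in atoms if a.name in table[resname]]
            if not coords:
                log.info("charged residue %s %s lacks side-chain atoms; "
                         "skipped", resname, key)
                continue
            out.append((key, np.asarray(coords, dtype=float)))
        return out

    basics = group_atoms(basic_names)
    acidics = group_atoms(ACIDIC_GROUP_ATOMS)
    bridges = []
    for bkey, bxyz in basics:
        for akey, axyz in acidics:
            if bkey == akey:
                continue
            d = float(cdist(bxyz, axyz).min())
            if d <= cutoff:
                bridges.append(SaltBridge(basic=bkey, acidic=akey, distance=d))
    bridges.sort(key=lambda b: (b.basic, b.acidic))
    return bridges


# Side-chain N/O atoms able to donate / accept a hydrogen bond, per residue.
_SIDECHAIN_DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"}, "GLN": {"OE1"}, "HIS": {"ND1", "NE2"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}


def _polar_role(atom) -> tuple[bool, bool]:
    """(can_donate, can_accept) for a heavy atom, hydrogens unseen."""
    if atom.is_backbone:
        if atom.name == "N":
            return True, False
        if atom.name in ("O", "OXT"):
            return False, True
        return False, False
    donors = _SIDECHAIN_DONOR_ATOMS.get(atom.residue_name, set())
    acceptors = _SIDECHAIN_ACCEPTOR_ATOMS.get(atom.residue_name, set())
    return atom.name in donors, atom.name in acceptors


def detect_hbonds(s: StructureModel, d_cutoff: float = 3.5) -> list[HydrogenBond]:
    """Donor/acceptor N,O heavy-atom pairs within ``d_cutoff`` Å.

    Pairs within one residue are never reported; backbone N–O contacts of
    adjacent residues below 2.0 Å are covalent amide geometry and are
    excluded. Each unordered pair is reported once (donor listed first).
    """
    polar = []
    for i, a in enumerate(s.atoms):
        don, acc = _polar_role(a)
        if don or acc:
            polar.append((i, a, don, acc))
    if not polar:
        return []
    xyz = np.array([a.coord for _, a, _, _ in polar])
    dmat = cdist(xyz, xyz)
    bonds = []
    seen: set[frozenset] = set()
    for p in range(len(polar)):
        for q in range(p + 1, len(polar)):
            d = float(dmat[p, q])
            if d > d_cutoff:
                continue
            _, a, a_don, a_acc = polar[p]
            _, b, b_don, b_acc = polar[q]
            ra = (a.chain, a.residue_number)
            rb = (b.chain, b.residue_number)
            if ra == rb:
                continue
            if (a.chain == b.chain and abs(a.residue_number - b.residue_number) == 1
                    and a.is_backbone and b.is_backbone and d < 2.0):
                continue
            # orient donor -> acceptor; try both directions
            if a_don and b_acc:
                donor, acceptor = a, b
            elif b_don and a_acc:
                donor, acceptor = b, a
            else:
                continue
            pair_key = frozenset([(ra, a.name), (rb, b.name)])
            if pair_key in seen:
                continue
            seen.add(pair_key)
            bonds.append(HydrogenBond(
                donor_residue=(donor.chain, donor.residue_number),
                donor_atom=donor.name,
                acceptor_residue=(acceptor.chain, acceptor.residue_number),
                acceptor_atom=acceptor.name,
                distance=d,
                donor_is_sidechain=not donor.is_backbone,
                acceptor_is_sidechain=not acceptor.is_backbone,
            ))
    bonds.sort(key=lambda h: (h.donor_residue, h.acceptor_residue, h.distance))
    return bonds


def build_inventory(s: StructureModel, salt_bridge_cutoff: float = 4.0,
                    hbond_cutoff: float = 3.5,
                    include_his: bool = True) -> InteractionInventory:
    return InteractionInventory(
        salt_bridges=detect_salt_bridges(s, cutoff=salt_bridge_cutoff,
                                         include_his=include_his),
        hbonds=detect_hbonds(s, d_cutoff=hbond_cutoff),
    )
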