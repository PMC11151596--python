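"""Synthetic structures and prediction tables with planted ground truth.

Every screening stage can be tested without downloading anything: a toy
structure is a chain of alanine-like residues laid out on a widely spaced
line (so no unplanted contacts arise), into which salt bridges, hydrogen
bonds, and buried/exposed sites are planted at exact, requested
geometries. Side-chain proxy atoms carry real PDB atom names (NZ, OE1,
OG, ...) on simplified geometry, so the screening modules parse fixtures
through exactly the code paths used for real files.

Fixtures are geometric, not energetic: bond lengths and conformations are
idealised and no physical plausibility is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .predictors import PredictionTable
from .sasa import sphere_points
from .structure import Atom, StructureModel

#: Spacing between consecutive residue anchors (Å); wide enough that no
#: unplanted pair of charged groups can approach the 4.5 Å guard radius.
RESIDUE_SPACING = 7.5

#: Cage shells (radius Å, n atoms) used to bury a site.
CAGE_SHELLS = ((4.5, 120), (7.0, 260))

#: Minimum heavy-atom contact distance an interaction can be planted at.
MIN_PLANT_DISTANCE = 2.4


@dataclass(frozen=True)
class ToyStructureSpec:
    """Recipe for a synthetic structure; generation is a pure function
    of this spec (byte-identical PDB output for equal specs)."""

    n_residues: int
    planted_salt_bridges: tuple = ()   # (pos_i, pos_j, distance Å)
    planted_hbonds: tuple = ()         # (pos_i, pos_j, distance Å)
    buried_sites: tuple = ()
    exposed_sites: tuple = ()
    seed: int = 0
    chain: str = "A"

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_salt_bridges",
                           tuple(tuple(p) for p in self.planted_salt_bridges))
        object.__setattr__(self, "planted_hbonds",
                           tuple(tuple(p) for p in self.planted_hbonds))
        object.__setattr__(self, "buried_sites", tuple(self.buried_sites))
        object.__setattr__(self, "exposed_sites", tuple(self.exposed_sites))
        for i, j, d in list(self.planted_salt_bridges) + list(self.planted_hbonds):
            if i == j:
                raise ValueError(f"planted pair at a single residue: {i}")
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise ValueError(f"planted pair ({i},{j}) outside chain")
            if d < MIN_PLANT_DISTANCE:
                raise ValueError(
                    f"infeasible spec: planted distance {d} Å below vdW "
                    f"contact ({MIN_PLANT_DISTANCE} Å)")

    @classmethod
    def from_yaml(cls, path) -> "ToyStructureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _format_pdb_line(a: Atom) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3}"
    x, y, z = a.coord
    return (f"ATOM  {a.serial:5d} {name}{'':1}{a.residue_name:>3} "
            f"{a.chain}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}")


def structure_to_pdb_string(s: StructureModel) -> str:
    """Fixed-column PDB text; stable byte-for-byte for equal structures."""
    return "\n".join(_format_pdb_line(a) for a in s.atoms) + "\nEND\n"


def write_pdb(s: StructureModel, path) -> None:
    Path(path).write_text(structure_to_pdb_string(s))


def make_toy_structure(spec: ToyStructureSpec,
                       path=None) -> StructureModel:
    """Build a structure realising the spec's planted interactions.

    Residues sit on a line at 7.5 Å spacing, each with an idealised
    N/CA/C/O backbone and a CB. A planted salt bridge turns residue i
    into LYS (NZ) and j into GLU (OE1), the two charged atoms facing each
    other across the midpoint of their anchors at exactly the requested
    distance; a planted hydrogen bond does the same with two SER OG
    atoms. A buried site is caged inside two concentric shells of
    CA-only glycine pseudo-residues (numbered from 9001) so its relative
    SASA drops below the buried threshold. If ``path`` is given the
    structure is also written as PDB.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    jitter = rng.uniform(-0.2, 0.2, size=(n, 2))  # y/z wobble, breaks collinearity

    resnames = {i: "ALA" for i in range(1, n + 1)}
    special_atoms: dict[int, list[tuple[str, np.ndarray]]] = {i: [] for i in resnames}

    anchors = {}
    for i in range(1, n + 1):
        anchors[i] = np.array([RESIDUE_SPACING * i,
                               jitter[i - 1, 0], jitter[i - 1, 1]])

    def plant_pair(i, j, d, res_i, atom_i, res_j, atom_j, channel):
        for pos, res in ((i, res_i), (j, res_j)):
            if resnames[pos] not in ("ALA", res):
                raise ValueError(
                    f"residue {pos} used by two incompatible plantings")
            resnames[pos] = res
        # the pair sits in a lateral channel below the backbone line so the
        # connecting segment cannot thread through intervening residues;
        # channels are staggered in z per planting
        lateral = np.array([0.0, -4.5, 2.5 * channel])
        mid = (anchors[i] + anchors[j]) / 2.0 + lateral
        direction = anchors[j] - anchors[i]
        direction = direction / np.linalg.norm(direction)
        special_atoms[i].append((atom_i, mid - direction * (d / 2.0)))
        special_atoms[j].append((atom_j, mid + direction * (d / 2.0)))

    channel = 0
    for i, j, d in spec.planted_salt_bridges:
        plant_pair(i, j, d, "LYS", "NZ", "GLU", "OE1", channel)
        channel += 1
    for i, j, d in spec.planted_hbonds:
        plant_pair(i, j, d, "SER", "OG", "SER", "OG", channel)
        channel += 1

    atoms: list[Atom] = []
    serial = 0

    def add(name, resname, resnum, coord, element):
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial=serial, name=name, residue_name=resname,
                          chain=spec.chain, residue_number=resnum,
                          coord=(round(float(coord[0]), 3),
                                 round(float(coord[1]), 3),
                                 round(float(coord[2]), 3)),
                          element=element))

    backbone_offsets = (
        ("N", np.array([-1.45, 0.50, 0.0]), "N"),
        ("CA", np.array([0.0, 0.0, 0.0]), "C"),
        ("C", np.array([1.50, 0.30, 0.0]), "C"),
        ("O", np.array([1.80, 1.50, 0.0]), "O"),
        ("CB", np.array([0.0, -1.53, 0.0]), "C"),
    )
    for i in range(1, n + 1):
        for name, off, el in backbone_offsets:
            add(name, resnames[i], i, anchors[i] + off, el)
        for name, coord in special_atoms[i]:
            add(name, resnames[i], i, coord, name[0])

    cage_serial_start = 9000
    cage_num = cage_serial_start
    for site in spec.buried_sites:
        center = anchors[site] + np.array([0.0, -0.75, 0.0])
        for radius, n_pts in CAGE_SHELLS:
            for p in sphere_points(n_pts):
                cage_num += 1
                add("CA", "GLY", cage_num, center + radius * p, "C")

    s = StructureModel(atoms=atoms)
    _check_no_spurious_contacts(s, spec)
    if path is not None:
        write_pdb(s, path)
    return s


def _check_no_spurious_contacts(s: StructureModel,
                                spec: ToyStructureSpec,
                                guard: float = 4.5) -> None:
    planted = {frozenset((i, j)) for i, j, _ in spec.planted_salt_bridges}
    charged = [a for a in s.atoms if a.name in ("NZ", "OE1")]
    for a in charged:
        for b in charged:
            if a.name == b.name or a.residue_number >= b.residue_number:
                continue
            pair = frozenset((a.residue_number, b.residue_number))
            d = math.dist(a.coord, b.coord)
            if pair not in planted and d < guard:
                raise ValueError(
                    f"infeasible spec: unplanted charged pair "
                    f"{sorted(pair)} at {d:.2f} Å")


def make_toy_predictions(variants: list[str], seed: int,
                         wt_pair: tuple[float, float],
                         noise_sigma: float = 0.0,
                         sequence_id: str = "toy",
                         substrate: str = "toy-substrate",
                         ) -> tuple[PredictionTable, PredictionTable]:
    """Paired K1/K2 tables with a known scale factor between them.

    K1 kcats are lognormal around ``k1_wt``; K2 equals ``factor * K1``
    (factor = k2_wt / k1_wt) with optional per-variant multiplicative
    lognormal noise of width ``noise_sigma``. The WT records are exact in
    both tables, so with zero noise the calibrate→combine round trip
    recovers the K2 table identically (parameter-recovery harness).
    """
    k1_wt, k2_wt = wt_pair
    if k1_wt <= 0 or k2_wt <= 0:
        raise ValueError(f"wt_pair must be positive, got {wt_pair}")
    rng = np.random.default_rng(seed)
    factor = k2_wt / k1_wt
    k1 = PredictionTable(predictor_id="toy-k1", sequence_id=sequence_id,
                         substrate_smiles=substrate)
    k2 = PredictionTable(predictor_id="toy-k2", sequence_id=sequence_id,
                         substrate_smiles=substrate)
    k1.add("WT", k1_wt)
    k2.add("WT", k2_wt)
    for label in variants:
        v1 = k1_wt * float(np.exp(rng.normal(0.0, 0.5)))
        noise = float(np.exp(rng.normal(0.0, noise_sigma))) if noise_sigma else 1.0
        k1.add(label, v1)
        k2.add(label, factor * v1 * noise)
    return k1, k2
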