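"""PDB parsing, salt-bridge and hydrogen-bond detection.

Detection is checked against brute-force all-pairs distance oracles on
randomly generated structures, and against planted ground truth from the
toy-structure generator.
"""

import math

import numpy as np
import pytest

import kcatscreen as ks
from kcatscreen.interactions import (ACIDIC_GROUP_ATOMS, BASIC_GROUP_ATOMS,
                                     detect_hbonds, detect_salt_bridges)
from kcatscreen.structure import Atom, StructureModel


def atom(serial, name, resname, resnum, xyz, element=None, chain="A",
         occupancy=1.0):
    return Atom(serial=serial, name=name, residue_name=resname, chain=chain,
                residue_number=resnum, coord=tuple(float(v) for v in xyz),
                element=element or name[0], occupancy=occupancy)


def build(atoms):
    return StructureModel(atoms=list(atoms))


PDB_ATOM = ("ATOM      1  CA  ALA A   1      11.104  13.207   2.100"
            "  1.00 20.00           C")


class TestReadPdb:
    def test_single_atom_line(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_ATOM + "\nEND\n")
        s = ks.read_pdb(p)
        a = s.atoms[0]
        assert a.name == "CA" and a.residue_name == "ALA"
        assert a.coord == pytest.approx((11.104, 13.207, 2.1))
        assert a.element == "C"

    def test_altloc_highest_occupancy_of_preferred(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.60 20.00           C",
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000"
            "  0.40 20.00           C",
        ]
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        s = ks.read_pdb(p)
        assert len(s.atoms) == 1
        assert s.atoms[0].coord[0] == pytest.approx(0.0)  # altloc A kept

    def test_hetatm_only_is_error(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text("HETATM    1  O   HOH A 401      0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        with pytest.raises(ValueError, match="no ATOM records"):
            ks.read_pdb(p)

    def test_waters_excluded(self, tmp_path):
        p = tmp_path / "mix.pdb"
        p.write_text(PDB_ATOM + "\n"
                     "HETATM    2  O   HOH A 401      0.000   0.000   0.000"
                     "  1.00  0.00           O\nEND\n")
        s = ks.read_pdb(p)
        assert len(s.atoms) == 1

    def test_chain_selection_default_first(self, tmp_path):
        lines = [PDB_ATOM,
                 PDB_ATOM.replace(" A   1 ", " B   1 ").replace(
                     "ATOM      1", "ATOM      2")]
        p = tmp_path / "two.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        assert {a.chain for a in ks.read_pdb(p).atoms} == {"A"}
        assert {a.chain for a in ks.read_pdb(p, chain="B").atoms} == {"B"}

    def test_missing_calpha_flagged(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text("ATOM      1  N   ALA A   1      0.000   0.000   0.000"
                     "  1.00 20.00           N\nEND\n")
        s = ks.read_pdb(p)
        assert ("A", 1) in s.flagged_residues


class TestSaltBridges:
    def test_pair_inside_cutoff(self):
        s = build([
            atom(1, "CA", "LYS", 1, (0, 0, 0)),
            atom(2, "NZ", "LYS", 1, (0, 0, 1)),
            atom(3, "CA", "GLU", 2, (10, 0, 0)),
            atom(4, "OE1", "GLU", 2, (0, 0, 4.5)),
        ])
        bridges = detect_salt_bridges(s, cutoff=4.0)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.5)
        assert bridges[0].basic == ("A", 1) and bridges[0].acidic == ("A", 2)

    def test_pair_outside_cutoff(self):
        s = build([
            atom(1, "NZ", "LYS", 1, (0, 0, 0)),
            atom(2, "OE1", "GLU", 2, (0, 0, 4.5)),
        ])
        assert detect_salt_bridges(s, cutoff=4.0) == []

    def test_histidine_toggle(self):
        s = build([
            atom(1, "NE2", "HIS", 1, (0, 0, 0)),
            atom(2, "OD1", "ASP", 2, (0, 0, 3.0)),
        ])
        assert len(detect_salt_bridges(s, include_his=True)) == 1
        assert detect_salt_bridges(s, include_his=False) == []

    def test_monotone_in_cutoff(self):
        s = build([
            atom(1, "NZ", "LYS", 1, (0, 0, 0)),
            atom(2, "OE1", "GLU", 2, (0, 0, 3.9)),
            atom(3, "NH1", "ARG", 3, (0, 0, 8.0)),
        ])
        small = {(b.basic, b.acidic) for b in detect_salt_bridges(s, cutoff=3.0)}
        large = {(b.basic, b.acidic) for b in detect_salt_bridges(s, cutoff=4.5)}
        assert small <= large

    def test_matches_brute_force_oracle_on_random_structures(self):
        rng = np.random.default_rng(42)
        charged = [("LYS", ["NZ"]), ("ARG", ["NH1", "NH2", "NE"]),
                   ("HIS", ["ND1", "NE2"]), ("ASP", ["OD1", "OD2"]),
                   ("GLU", ["OE1", "OE2"])]
        for trial in range(10):
            atoms, serial = [], 0
            for resnum in range(1, 31):
                resname, names = charged[rng.integers(len(charged))]
                base = rng.uniform(0, 25, size=3)
                for name in names:
                    serial += 1
                    atoms.append(atom(serial, name, resname, resnum,
                                      base + rng.uniform(-1, 1, size=3)))
            s = build(atoms)
            got = {(b.basic, b.acidic, round(b.distance, 6))
                   for b in detect_salt_bridges(s, cutoff=4.0)}
            # oracle: exhaustive loops over charged-group atom pairs
            expected = set()
            for (bres, bname) in {(a.residue_number, a.residue_name)
                                  for a in atoms
                                  if a.residue_name in BASIC_GROUP_ATOMS}:
                for (ares, aname) in {(a.residue_number, a.residue_name)
                                      for a in atoms
                                      if a.residue_name in ACIDIC_GROUP_ATOMS}:
                    ds = [math.dist(x.coord, y.coord)
                          for x in atoms for y in atoms
                          if x.residue_number == bres
                          and x.name in BASIC_GROUP_ATOMS[bname]
                          and y.residue_number == ares
                          and y.name in ACIDIC_GROUP_ATOMS[aname]]
                    if ds and min(ds) <= 4.0:
                        expected.add((("A", bres), ("A", ares),
                                      round(min(ds), 6)))
            assert got == expected


class TestHydrogenBonds:
    def test_backbone_pair_at_published_distance(self):
        # carbonyl O and amide N, two residues apart, at 2.84 A
        s = build([
            atom(1, "O", "CYS", 172, (0, 0, 0)),
            atom(2, "CA", "CYS", 172, (1.5, 0, 0)),
            atom(3, "N", "ASP", 174, (0, 0, 2.84)),
            atom(4, "CA", "ASP", 174, (1.5, 0, 2.84)),
        ])
        bonds = detect_hbonds(s)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.84)

    def test_outside_cutoff_not_detected(self):
        s = build([
            atom(1, "O", "ALA", 1, (0, 0, 0)),
            atom(2, "N", "ALA", 3, (0, 0, 3.8)),
        ])
        assert detect_hbonds(s, d_cutoff=3.5) == []

    def test_same_residue_never_reported(self):
        s = build([
            atom(1, "O", "SER", 1, (0, 0, 0)),
            atom(2, "OG", "SER", 1, (0, 0, 2.84)),
        ])
        assert detect_hbonds(s) == []

    def test_covalent_backbone_geometry_excluded(self):
        s = build([
            atom(1, "O", "ALA", 1, (0, 0, 0)),
            atom(2, "N", "ALA", 2, (0, 0, 1.9)),
        ])
        assert detect_hbonds(s) == []

    def test_sidechain_flags(self):
        s = build([
            atom(1, "OG", "SER", 1, (0, 0, 0)),
            atom(2, "O", "ALA", 5, (0, 0, 3.0)),
        ])
        (hb,) = detect_hbonds(s)
        assert hb.donor_is_sidechain and not hb.acceptor_is_sidechain

    def test_matches_brute_force_oracle_on_random_structures(self):
        from kcatscreen.interactions import _polar_role
        rng = np.random.default_rng(7)
        for trial in range(10):
            atoms, serial = [], 0
            for resnum in range(1, 41):
                base = rng.uniform(0, 30, size=3)
                for name, resname in (("N", "SER"), ("O", "SER"),
                                      ("OG", "SER")):
                    serial += 1
                    atoms.append(atom(serial, name, resname, resnum,
                                      base + rng.uniform(-1, 1, size=3)))
            s = build(atoms)
            got = {frozenset([(h.donor_residue, h.donor_atom),
                              (h.acceptor_residue, h.acceptor_atom)])
                   for h in detect_hbonds(s, d_cutoff=3.5)}
            expected = set()
            for x in atoms:
                for y in atoms:
                    if x.serial >= y.serial:
                        continue
                    if x.residue_number == y.residue_number:
                        continue
                    d = math.dist(x.coord, y.coord)
                    if d > 3.5:
                        continue
                    if (abs(x.residue_number - y.residue_number) == 1
                            and x.is_backbone and y.is_backbone and d < 2.0):
                        continue
                    xd, xa = _polar_role(x)
                    yd, ya = _polar_role(y)
                    if (xd and ya) or (yd and xa):
                        expected.add(frozenset([
                            ((x.chain, x.residue_number), x.name),
                            ((y.chain, y.residue_number), y.name)]))
            assert got == expected


class TestPlantedGroundTruth:
    def test_planted_interactions_recovered(self, toy_structure, toy_spec):
        bridges = detect_salt_bridges(toy_structure)
        assert [(b.basic[1], b.acidic[1]) for b in bridges] == \
            [(i, j) for i, j, _ in toy_spec.planted_salt_bridges]
        assert bridges[0].distance == pytest.approx(3.5, abs=0.05)
        side = [h for h in detect_hbonds(toy_structure)
                if h.donor_is_sidechain and h.acceptor_is_sidechain]
        assert len(side) == 1
        assert side[0].distance == pytest.approx(2.84, abs=0.05)
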