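"""Shrake–Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius (water, 1.4 Å) and sampled with
a deterministic spherical point set (golden-section spiral); a point is
accessible if it lies outside every neighbouring atom's inflated sphere.
Per-residue SASA sums the residue's atoms; relative SASA divides by the
residue type's theoretical maximum (Tien et al. 2013 values), giving the
standard surface/buried classification scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureModel

log = logging.getLogger(__name__)

#: Van der Waals radii (Å) used for SASA; unknown elements fall back to C.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
FALLBACK_RADIUS = 1.70

#: Theoretical maximum accessible surface area per residue type (Å²),
#: Tien et al. 2013 (theoretical column), for relative-SASA normalisation.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))       # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radius(element: str, overrides: dict[str, float] | None = None) -> float:
    table = {**VDW_RADII, **(overrides or {})}
    el = element.upper()
    if el not in table:
        log.warning("unknown element %r: using fallback vdW radius %.2f Å",
                    element, FALLBACK_RADIUS)
        return FALLBACK_RADIUS
    return table[el]


@dataclass
class SasaResult:
    atom_sasa: np.ndarray                      # Å² per atom
    residue_sasa: dict[tuple[str, int], float]
    relative_sasa: dict[tuple[str, int], float]

    def rel(self, chain: str, resnum: int) -> float:
        return self.relative_sasa[(chain, resnum)]


def compute_sasa(s: StructureModel, probe: float = 1.4,
                 n_points: int = 960,
                 radii_overrides: dict[str, float] | None = None) -> SasaResult:
    """Shrake–Rupley SASA for every atom, summed per residue.

    ``n_points`` sample points per atom (default 960; error vs the
    analytic sphere is well under 1% there). Relative SASA uses the
    residue-type maxima in :data:`MAX_SASA`; residue types outside the
    canonical 20 get relative SASA 0 (they never participate in the
    surface-hydrophobicity rule anyway).
    """
    xyz = s.coords()
    radii = np.array([atom_radius(a.element, radii_overrides)
                      for a in s.atoms]) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * radii.max()
    atom_sasa = np.zeros(len(s.atoms))
    for i in range(len(s.atoms)):
        pts = xyz[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], max_reach):
            if j == i:
                continue
            d = np.linalg.norm(xyz[i] - xyz[j])
            if d >= radii[i] + radii[j]:
                continue
            accessible &= (np.linalg.norm(pts - xyz[j], axis=1) >= radii[j])
            if not accessible.any():
                break
        atom_sasa[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2

    residue_sasa: dict[tuple[str, int], float] = {}
    relative: dict[tuple[str, int], float] = {}
    for key, resname, atoms in s.residues():
        idx = s.residue_index[key]
        total = float(atom_sasa[idx].sum())
        residue_sasa[key] = total
        max_area = MAX_SASA.get(resname)
        relative[key] = total / max_area if max_area else 0.0
    return SasaResult(atom_sasa=atom_sasa, residue_sasa=residue_sasa,
                      relative_sasa=relative)
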