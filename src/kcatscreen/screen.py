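"""Structure-based exclusion screening of candidate point mutations.

Three criteria, judged on the wild-type structure only (no mutant
modelling):

1. interaction disruption — the wild-type side chain takes part in a
   detected salt bridge or hydrogen bond and the substituting residue
   loses the chemical class needed to maintain it (charge class for salt
   bridges; donor/acceptor capability for H-bonds). E→Q keeps an H-bond
   acceptor but loses the charge, so it disrupts a salt bridge but not
   necessarily an H-bond.
2. steric clash — a volume-bookkeeping heuristic: the free volume in a
   shell around the site's C-beta must accommodate the new side chain's
   tabulated volume. Not rotamer sampling; the margin is reported so
   borderline calls can be audited.
3. surface hydrophobicity — a hydrophobic substituting residue at a
   solvent-exposed site (relative SASA above threshold).

Verdicts are pure functions of (structure, mutation, config). Sites that
cannot be mapped onto the structure fail closed with an UNMAPPED reason,
so silent numbering mismatches cannot pass candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .interactions import InteractionInventory, build_inventory
from .sasa import SasaResult, compute_sasa
from .sequence import Mutation
from .structure import ONE_TO_THREE, StructureModel

log = logging.getLogger(__name__)

REASON_SALT_BRIDGE = "SALT_BRIDGE_DISRUPTION"
REASON_HBOND = "HBOND_DISRUPTION"
REASON_CLASH = "STERIC_CLASH"
REASON_SURFACE = "SURFACE_HYDROPHOBIC"
REASON_UNMAPPED = "UNMAPPED"

BASIC_AA = set("RKH")
ACIDIC_AA = set("DE")

#: Residues whose side chain can donate / accept an H-bond (heavy-atom view).
SIDECHAIN_DONOR_AA = set("RKHWNQSTYC")
SIDECHAIN_ACCEPTOR_AA = set("DENQHSTYM")

#: Side-chain volumes (Å³): Zamyatnin residue volumes minus the glycine
#: backbone volume; glycine itself contributes no side-chain volume.
SIDECHAIN_VOLUME = {
    "A": 28.5, "R": 113.3, "N": 54.0, "D": 51.0, "C": 48.4,
    "Q": 83.7, "E": 78.3, "G": 0.0, "H": 93.1, "I": 106.6,
    "L": 106.6, "K": 108.5, "M": 102.8, "F": 129.8, "P": 52.6,
    "S": 28.9, "T": 56.0, "W": 167.7, "Y": 133.5, "V": 79.9,
}

ATOM_VDW_VOLUME = {el: 4.0 / 3.0 * np.pi * r ** 3
                   for el, r in {"C": 1.70, "N": 1.55, "O": 1.52,
                                 "S": 1.80}.items()}


@dataclass
class ScreenConfig:
    """Thresholds of the exclusion screen; every value is echoed in
    report headers so results are auditable."""

    salt_bridge_cutoff: float = 4.0      # Å, charged-group heavy atoms
    hbond_cutoff: float = 3.5            # Å, donor/acceptor heavy atoms
    rel_sasa_surface: float = 0.25       # surface ⟺ relative SASA ≥ this
    hydrophobic_aa: str = "AVLIMFWC"
    clash_shell: float = 5.0             # Å, free-volume shell radius
    clash_tolerance: float = 0.0         # Å³ slack before a clash fires
    include_his_salt_bridges: bool = True
    chain: str | None = None             # None: first chain in the file
    sasa_n_points: int = 960
    probe_radius: float = 1.4
    vdw_radii: dict = field(default_factory=dict)   # element → Å overrides

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown screen config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterVerdict:
    """Pass/fail for one mutation with reason codes and numeric evidence.

    ``passed`` is true exactly when ``reasons`` is empty; each reason key
    appears in ``diagnostics`` with the numbers that triggered it.
    """

    mutation: Mutation
    passed: bool
    reasons: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def pseudo_cbeta(n, ca, c) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C (used for glycine)."""
    n, ca, c = (np.asarray(v, dtype=float) for v in (n, ca, c))
    b1 = n - ca
    b2 = c - ca
    b1 /= np.linalg.norm(b1)
    b2 /= np.linalg.norm(b2)
    bisector = -(b1 + b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp)
    # tetrahedral geometry, 1.53 Å bond
    direction = bisector * np.cos(0.954) + perp * np.sin(0.954)
    return ca + 1.53 * direction / np.linalg.norm(direction)


def _site_point(s: StructureModel, chain: str, resnum: int) -> np.ndarray:
    atoms = {a.name: np.asarray(a.coord) for a in s.residue_atoms(chain, resnum)}
    if "CB" in atoms:
        return atoms["CB"]
    if all(k in atoms for k in ("N", "CA", "C")):
        return pseudo_cbeta(atoms["N"], atoms["CA"], atoms["C"])
    return atoms.get("CA", next(iter(atoms.values())))


def assess_clash(s: StructureModel, m: Mutation, chain: str | None = None,
                 shell: float = 5.0, tolerance: float = 0.0,
                 numbering_offset: int = 0) -> tuple[bool, float]:
    """Steric-clash heuristic at a mutation site.

    Free volume = shell-sphere volume around the site's C-beta (projected
    for glycine) minus the vdW volumes of neighbouring heavy atoms (other
    residues) whose centres fall inside the shell. A clash fires when the
    substituting side chain's tabulated volume exceeds the free volume
    plus tolerance. Glycine never clashes. Returns ``(clash, margin)``
    with margin = free − required (Å³; negative means clash).
    """
    chain = chain or s.chains[0]
    resnum = m.position + numbering_offset
    if not s.has_residue(chain, resnum):
        raise KeyError(f"residue {chain}/{resnum} absent from structure")
    center = _site_point(s, chain, resnum)
    shell_volume = 4.0 / 3.0 * np.pi * shell ** 3
    occupied = 0.0
    for a in s.atoms:
        if (a.chain, a.residue_number) == (chain, resnum):
            continue
        if np.linalg.norm(np.asarray(a.coord) - center) <= shell:
            occupied += ATOM_VDW_VOLUME.get(a.element.upper(),
                                            ATOM_VDW_VOLUME["C"])
    free = shell_volume - occupied
    required = SIDECHAIN_VOLUME[m.mut_aa]
    margin = free - required
    if m.mut_aa == "G":
        return False, margin
    return required > free + tolerance, margin


@dataclass
class ScreenContext:
    """Inventory and SASA computed once per structure and reused for
    every mutation verdict."""

    structure: StructureModel
    config: ScreenConfig
    inventory: InteractionInventory
    sasa: SasaResult
    chain: str

    @classmethod
    def build(cls, s: StructureModel, cfg: ScreenConfig) -> "ScreenContext":
        chain = cfg.chain or s.chains[0]
        inventory = build_inventory(
            s, salt_bridge_cutoff=cfg.salt_bridge_cutoff,
            hbond_cutoff=cfg.hbond_cutoff,
            include_his=cfg.include_his_salt_bridges)
        sasa = compute_sasa(s, probe=cfg.probe_radius,
                            n_points=cfg.sasa_n_points,
                            radii_overrides=cfg.vdw_radii or None)
        return cls(structure=s, config=cfg, inventory=inventory,
                   sasa=sasa, chain=chain)


def _judge(ctx: ScreenContext, m: Mutation,
           numbering_offset: int) -> FilterVerdict:
    cfg = ctx.config
    s = ctx.structure
    resnum = m.position + numbering_offset
    key = (ctx.chain, resnum)

    if not s.has_residue(*key):
        return FilterVerdict(
            mutation=m, passed=False, reasons=(REASON_UNMAPPED,),
            diagnostics={REASON_UNMAPPED: {
                "chain": ctx.chain, "residue_number": resnum,
                "detail": "site absent from structure"}})
    resname = s.residue_name(*key)
    expected = ONE_TO_THREE.get(m.wt_aa)
    if resname != expected:
        return FilterVerdict(
            mutation=m, passed=False, reasons=(REASON_UNMAPPED,),
            diagnostics={REASON_UNMAPPED: {
                "chain": ctx.chain, "residue_number": resnum,
                "detail": f"structure has {resname}, mutation expects "
                          f"{expected}"}})

    reasons: list[str] = []
    diagnostics: dict = {}

    # criterion 1a: salt-bridge disruption by charge-class loss
    bridges = ctx.inventory.bridges_of(key)
    if bridges:
        wt_class = BASIC_AA if m.wt_aa in BASIC_AA else ACIDIC_AA
        if m.mut_aa not in wt_class:
            reasons.append(REASON_SALT_BRIDGE)
            diagnostics[REASON_SALT_BRIDGE] = {
                "n_bridges": len(bridges),
                "min_distance": min(b.distance for b in bridges),
            }

    # criterion 1b: H-bond disruption by donor/acceptor capability loss
    hbonds = ctx.inventory.sidechain_hbonds_of(key)
    if hbonds:
        wt_roles = {r for r, members in
                    (("donor", SIDECHAIN_DONOR_AA),
                     ("acceptor", SIDECHAIN_ACCEPTOR_AA)) if m.wt_aa in members}
        mut_roles = {r for r, members in
                     (("donor", SIDECHAIN_DONOR_AA),
                      ("acceptor", SIDECHAIN_ACCEPTOR_AA)) if m.mut_aa in members}
        if wt_roles and not (wt_roles & mut_roles):
            reasons.append(REASON_HBOND)
            diagnostics[REASON_HBOND] = {
                "n_hbonds": len(hbonds),
                "min_distance": min(h.distance for h in hbonds),
                "lost_roles": sorted(wt_roles),
            }

    # criterion 2: steric clash
    clash, margin = assess_clash(
        s, m, chain=ctx.chain, shell=cfg.clash_shell,
        tolerance=cfg.clash_tolerance, numbering_offset=numbering_offset)
    if clash:
        reasons.append(REASON_CLASH)
        diagnostics[REASON_CLASH] = {"volume_margin": margin}

    # criterion 3: hydrophobic residue introduced at a surface site
    rel = ctx.sasa.rel(*key)
    if m.mut_aa in cfg.hydrophobic_aa and rel >= cfg.rel_sasa_surface:
        reasons.append(REASON_SURFACE)
        diagnostics[REASON_SURFACE] = {"relative_sasa": rel}

    return FilterVerdict(mutation=m, passed=not reasons,
                         reasons=tuple(reasons), diagnostics=diagnostics)


def apply_exclusion_criteria(mutations: list[Mutation], s: StructureModel,
                             cfg: ScreenConfig | None = None,
                             numbering_offset: int = 0,
                             context: ScreenContext | None = None
                             ) -> list[FilterVerdict]:
    """Screen every mutation against the three exclusion criteria.

    The interaction inventory and SASA are computed once and cached in a
    :class:`ScreenContext`; verdicts are independent of list order.
    """
    cfg = cfg or ScreenConfig()
    ctx = context or ScreenContext.build(s, cfg)
    return [_judge(ctx, m, numbering_offset) for m in mutations]


def write_verdicts_tsv(verdicts: list[FilterVerdict], path,
                       cfg: ScreenConfig | None = None) -> None:
    """Verdict TSV: ``mutation\\tpassed\\treasons\\tdiagnostics_json``,
    with the screen thresholds echoed as ``#`` header lines."""
    lines = []
    if cfg is not None:
        lines += [f"# {k}={v}" for k, v in sorted(cfg.to_dict().items())]
    lines.append("mutation\tpassed\treasons\tdiagnostics_json")
    for v in verdicts:
        lines.append("\t".join([
            str(v.mutation), str(v.passed).lower(), ",".join(v.reasons),
            json.dumps(v.diagnostics, sort_keys=True)]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_verdicts_tsv(path) -> list[FilterVerdict]:
    rows = [r for r in Path(path).read_text().splitlines()
            if r.strip() and not r.startswith("#")]
    if not rows or rows[0].split("\t")[:2] != ["mutation", "passed"]:
        raise ValueError(f"not a verdict TSV: {path}")
    out = []
    for row in rows[1:]:
        mut, passed, reasons, diag = row.split("\t")
        out.append(FilterVerdict(
            mutation=Mutation.parse(mut), passed=passed == "true",
            reasons=tuple(r for r in reasons.split(",") if r),
            diagnostics=json.loads(diag)))
    return out
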