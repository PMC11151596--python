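# Methods

## Scope and model of the workflow

`kcatscreen` operationalises a screening funnel for enzyme engineering:
exhaustive single-substitution enumeration → kcat prediction by an
ensemble of two external models → structure-based exclusion → per-locus
winner selection → combinatorial multi-point proposal. The package's own
contribution is the plumbing and the screening geometry; the kcat
predictors themselves are deliberately external. They enter through a
TSV contract (one `variant → kcat` table per predictor, kcat in s⁻¹),
never by in-process invocation, which keeps the repository free of
trained weights and GPU dependencies. Tables printed in min⁻¹ must be
converted by the caller (`per_minute_to_per_second`, ×1/60).

Sequences are 1-based; `numbering_offset` (default 0) maps sequence
positions onto the structure's author numbering, so mutation names like
`Q4C` address the same residue in both frames. Non-canonical residues
(X, B, Z, U) are rejected rather than skipped: both predictors and the
screening rules assume the canonical 20, and silently dropping positions
would desynchronise sequence and structure numbering.

## Ensemble calibration

Two kcat predictors applied to one enzyme typically agree in ranking
better than in scale. The default combination (`wt_ratio`) therefore
estimates a single dimensionless factor from the wild-type pair,
`factor = K2(WT)/K1(WT)`, and rescales the whole K1 table by it. Two
properties follow by construction and are enforced by tests: the variant
ranking under the combined table equals the K1 ranking (positive scalar
scaling), and `combined(WT) = K2(WT)` exactly. The calibration is
per-protein from one WT pair; nothing is learned across proteins.

A published form of the combination rule,
`[Max(k2/k1)/Min(k2/k1)]·Min(k2/k1)`, cancels algebraically to
`Max(k2/k1)` — a dimensionless ratio, not a turnover number — so it
cannot be used as a kcat. We ship it only as an audit diagnostic
(`max_ratio_diagnostic`, with Max/Min read over the per-variant ratio
set) and document both candidate readings rather than silently guessing
an intended behaviour. `geometric_mean` mode (√(K1·K2) over shared
variants) is offered for users who want both models to shape the
ranking; it is symmetric in its inputs.

## Screening geometry

All geometry is computed on the wild-type crystal structure;
"disruption" is judged by chemical-class loss of the substituting
residue, not by re-modelling the mutant. The rules in the source
workflow are qualitative, so each is operationalised with a standard
literature convention, exposed as a config key, and echoed into output
headers:

| parameter | default | meaning |
|---|---|---|
| `salt_bridge_cutoff` | 4.0 Å | max charged-group heavy-atom distance (Arg NH1/NH2/NE, Lys NZ, His ND1/NE2 × Asp OD1/OD2, Glu OE1/OE2) |
| `hbond_cutoff` | 3.5 Å | max donor/acceptor N,O heavy-atom distance (no hydrogens required) |
| `rel_sasa_surface` | 0.25 | relative SASA at or above which a site counts as surface |
| `hydrophobic_aa` | A,V,L,I,M,F,W,C | substitutions that trigger the surface-hydrophobicity rule |
| `clash_shell` | 5.0 Å | free-volume shell radius around the site Cβ |
| `clash_tolerance` | 0 Å³ | slack added to free volume before a clash fires |
| `include_his_salt_bridges` | true | count His as charged (protonation at assay pH is unknowable from the structure; toggleable) |
| `sasa_n_points` / `probe_radius` | 960 / 1.4 Å | Shrake–Rupley sampling density and solvent probe |

**Criterion 1 (interaction disruption).** A mutation is excluded when
the wild-type side chain participates in a detected salt bridge and the
substitution leaves the charge class (basic→non-basic, acidic→non-acidic),
or participates in a side-chain hydrogen bond and the substitution
retains none of the wild type's donor/acceptor capabilities. Backbone-
mediated bonds never exclude: every residue keeps its backbone.

**Criterion 2 (steric clash).** Free volume at the site is the 5 Å
shell volume around Cβ (projected tetrahedrally from N/CA/C for glycine)
minus the vdW volumes of neighbouring heavy atoms of other residues
inside the shell; a clash fires when the substituting side chain's
tabulated volume (Zamyatnin residue volumes minus the glycine backbone)
exceeds it. This is volume bookkeeping, not rotamer sampling — it cannot
see shape complementarity — so the signed margin is carried in the
verdict diagnostics for auditing borderline calls. Glycine never
clashes.

**Criterion 3 (surface hydrophobicity).** Excludes hydrophobic
substitutions at sites with relative SASA ≥ 0.25. We implement this
criterion exactly as worded. The workflow this package systematises
lists example exclusions under this rule (Q4R, Q4D, T212S, E303K) that
contradict the wording — R, D, S and K are not hydrophobic, and T212S
also appears among the selected winners — so that published example set
is not reproducible from any consistent rule; we record the discrepancy
here rather than reverse-engineering an undocumented behaviour.

Sites that cannot be mapped onto the structure (absent residue, or a
wild-type identity mismatch between mutation name and structure) fail
closed with a distinct `UNMAPPED` reason, so numbering errors surface as
exclusions rather than silent passes.

### SASA

Shrake–Rupley with a deterministic golden-spiral point set (960 points
per atom by default), probe 1.4 Å, and vdW radii C 1.70, N 1.55, O 1.52,
S 1.80 Å (unknown elements fall back to carbon with a warning). Checked
against the analytic sphere (error < 1% at 960 points) and the two-sphere
spherical-cap formula (< 2%). Relative SASA divides per-residue SASA by
the Tien et al. (2013) theoretical maxima; on sparse synthetic residues
(few atoms, no hydrogens) relative values can exceed 1, which is
harmless for thresholding. Raising the sampling density from 960 to
3840 points changes residue SASA by ≤ 2% away from zero.

### Hydrogen-bond adjacency rule

Intra-residue pairs are never reported; backbone N–O pairs of adjacent
residues are excluded only below 2.0 Å (covalent amide geometry). Real
adjacent backbone N–O contacts (~2.25 Å) can therefore appear in the
inventory; they are backbone-mediated and thus never contribute to an
exclusion, which consults side-chain bonds only.

## Per-locus selection and combination

Within each locus, the surviving mutation(s) of maximal combined kcat
are selected; exact floating-point ties keep all tied mutations, since a
tie is information (two equally ranked chemistries), not noise.
Combination proposal requires one winner per locus, so ties must be
resolved explicitly — `--tie-break alphabetical` or by editing the
winner list — with `error` as the default to avoid silently diverging
from user intent. Proposal enumerates all subsets of size 2..max_order
in lexicographic position order; three winners yield exactly three
doubles and one triple. In practice experimental triage sits between
selection and combination: the combinations worth building come from the
winners that validate at the bench, which is why `propose_combinations`
takes an explicit mutation list rather than wiring itself to the ranking
output.

## Synthetic fixtures

`make_toy_structure` builds structures with planted, exactly realised
interactions: residues on a widely spaced line (7.5 Å) of alanine-like
five-atom units; a planted salt bridge turns the pair into Lys(NZ)/
Glu(OE1) facing each other at the requested distance in a lateral
channel below the backbone (channels staggered per planting so plantings
cannot collide); hydrogen bonds use two Ser OG atoms the same way;
buried sites are caged inside two concentric shells of CA-only
pseudo-residues. Side-chain proxies use real PDB atom names on
simplified geometry, so the screening modules parse fixtures through
exactly the code paths used for real crystal structures. Generation is a
pure function of the spec (byte-identical PDB output), and planted
distances are realised within ±0.05 Å (coordinate rounding to 0.001 Å).

What the fixtures do **not** emulate: realistic backbone conformation,
side-chain rotamers, hydrogens, packing densities, altloc/occupancy
noise, or multi-chain assemblies. Passing tests on fixtures therefore
demonstrate the detectors' geometric correctness (against brute-force
all-pairs oracles and planted ground truth), not their biological error
rates on real structures.

`make_toy_predictions` emits paired K1/K2 tables at an exact scale
factor with optional lognormal per-variant noise (wild-type rows stay
exact so the calibration itself is never perturbed). With zero noise the
calibrate→combine round trip reproduces K2 identically — the
parameter-recovery harness; with noise σ the median relative deviation
of combined from K2 stays within 2σ.

The baseline kcat predictor is a hash-based surrogate (BLAKE2b-weighted
3-mer composition of sequence + substrate string, exponentiated): a pure,
platform-stable function of (sequence, substrate, seed), order- and
mutation-sensitive, strictly positive. It exists so the pipeline is
exercisable end to end and makes no scientific validity claim.

## Numerical and interface choices

- kcat unit is s⁻¹ everywhere; TSV round-trips are lossless to 6
  significant digits (documented precision of the format).
- Enumeration order (ascending position, then alphabetical substitution)
  and report generation are deterministic, so outputs are byte-stable
  across runs with fixed seeds.
- PDB altloc resolution keeps the blank/'A' conformer, breaking ties by
  occupancy; waters and HETATM records are excluded by default; the
  first chain is used unless one is named.
- Problem sizes in tests and the acceptance script (toy structures of
  12–50 residues, 1000-variant noise Monte Carlo) were chosen as the
  smallest sizes at which every property is non-trivially exercised —
  e.g. 50 residues gives 950 enumerated mutants and a multi-hundred-atom
  SASA computation.

## Known limitations

- The clash heuristic ignores side-chain shape and rotamer freedom; a
  large side chain in an anisotropic cavity can be mis-called either
  way. The margin diagnostic is the intended audit hook.
- Interaction disruption is class-based on the wild-type structure; it
  cannot detect a substitution that retains the class but breaks the
  geometry, nor compensating rearrangements in the mutant.
- His protonation, and hence its salt-bridge competence, is assumed, not
  computed.
- The ensemble calibrates from a single WT pair; an error in either WT
  prediction propagates multiplicatively into every combined value
  (ranking is unaffected in `wt_ratio` mode).
- No docking, molecular dynamics, ΔΔG, or thermostability prediction:
  the toolkit ranks candidates for experimental validation, it does not
  predict assay outcomes.
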