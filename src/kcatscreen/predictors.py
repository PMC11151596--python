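"""kcat predictor contract, TSV prediction tables, and a baseline surrogate.

External deep-learning turnover-number models (DLKcat-style sequence/substrate
networks, TurNuP-style models) integrate through the TSV interface: they are
run elsewhere and their per-variant predictions are loaded here. The built-in
baseline predictor exists so the whole pipeline is exercisable on any machine;
it is a deterministic hash-based surrogate with no scientific validity claim.

kcat values are stored in s^-1. Kinetic tables reported in min^-1 must be
converted by the caller (``per_minute_to_per_second``).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

from .sequence import Mutation, ProteinSequence, Variant, apply_variant, enumerate_saturation

RDLogger.DisableLog("rdApp.*")

#: Documented round-trip precision of the TSV format (significant digits).
TSV_SIG_DIGITS = 6


def per_minute_to_per_second(kcat_per_min: float) -> float:
    """Convert a turnover number from min^-1 to s^-1."""
    return kcat_per_min / 60.0


def validate_smiles(smiles: str) -> str:
    """Syntactic SMILES check via RDKit; returns the input unchanged."""
    if not smiles or Chem.MolFromSmiles(smiles, sanitize=False) is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return smiles


@dataclass
class PredictionTable:
    """Per-variant kcat predictions from one predictor.

    ``records`` maps canonical variant labels (ascending-position ``/``
    joined, or the literal ``"WT"``) to kcat in s^-1. At most one record
    per variant; the WT record is required before calibration.
    """

    predictor_id: str
    sequence_id: str = ""
    substrate_smiles: str = ""
    records: dict[str, float] = field(default_factory=dict)

    def add(self, variant_label: str, kcat: float) -> None:
        if variant_label in self.records:
            raise ValueError(f"duplicate variant {variant_label!r}")
        if not (math.isfinite(kcat) and kcat > 0):
            raise ValueError(
                f"kcat must be positive and finite, got {kcat!r} "
                f"for {variant_label!r}")
        self.records[variant_label] = float(kcat)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, variant_label: str) -> float:
        return self.records[variant_label]

    def __contains__(self, variant_label: str) -> bool:
        return variant_label in self.records

    @property
    def wt_kcat(self) -> float:
        if "WT" not in self.records:
            raise ValueError(
                f"table {self.predictor_id!r} has no WT record")
        return self.records["WT"]


def write_predictions_tsv(table: PredictionTable, path) -> None:
    """Write a table as TSV with ``#``-prefixed sidecar metadata lines.

    kcat is printed to 6 significant digits; a write→load round trip is
    lossless at that precision. Row order is deterministic (insertion
    order, which scans emit sorted)."""
    lines = [
        f"# predictor_id={table.predictor_id}",
        f"# sequence_id={table.sequence_id}",
        f"# substrate={table.substrate_smiles}",
        "variant\tkcat",
    ]
    lines += [f"{label}\t{kcat:.{TSV_SIG_DIGITS}g}"
              for label, kcat in table.records.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def load_predictions_tsv(path) -> PredictionTable:
    """Load a prediction TSV (header ``variant\\tkcat``; sidecar ``#`` lines
    ``predictor_id=``, ``sequence_id=``, ``substrate=``).

    Duplicate variants, non-positive or non-numeric kcat, a missing
    column and an empty file are all hard errors.
    """
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    rows: list[str] = []
    for raw in text.splitlines():
        if raw.startswith("#"):
            body = raw.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        elif raw.strip():
            rows.append(raw)
    if not rows:
        raise ValueError(f"empty prediction table: {path}")
    header = rows[0].split("\t")
    if "variant" not in header or "kcat" not in header:
        raise ValueError(
            f"missing required columns 'variant'/'kcat' in {path} "
            f"(found {header})")
    iv, ik = header.index("variant"), header.index("kcat")
    table = PredictionTable(
        predictor_id=meta.get("predictor_id", Path(path).stem),
        sequence_id=meta.get("sequence_id", ""),
        substrate_smiles=meta.get("substrate", ""),
    )
    for row in rows[1:]:
        cells = row.split("\t")
        label = cells[iv].strip()
        try:
            kcat = float(cells[ik])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"non-numeric kcat in row {row!r}") from exc
        table.add(label, kcat)
    return table


class BaselinePredictor:
    """Deterministic hash-based kcat surrogate for pipeline testing.

    Scores the hashed 3-mer composition of ``sequence + '|' + substrate``
    with weights derived from the seed (BLAKE2b, so identical across
    platforms and processes), then exponentiates so kcat > 0. It is a pure
    function of (sequence string, substrate string, seed), sensitive to
    residue order and to single substitutions. No scientific validity is
    claimed; it stands in for a trained model so the surrounding pipeline
    can be exercised without one.
    """

    K = 3  # k-mer width

    def __init__(self, seed: int, scale: float = 5.0):
        self.seed = int(seed)
        self.scale = float(scale)

    def _weight(self, kmer: str) -> float:
        h = hashlib.blake2b(f"{self.seed}:{kmer}".encode(),
                            digest_size=8).digest()
        # uniform in [-1, 1)
        return int.from_bytes(h, "big") / 2 ** 63 - 1.0

    def predict(self, seq: ProteinSequence, substrate_smiles: str) -> float:
        if len(seq.residues) == 0:
            raise ValueError("empty sequence")
        validate_smiles(substrate_smiles)
        text = seq.residues + "|" + substrate_smiles
        kmers = [text[i:i + self.K] for i in range(len(text) - self.K + 1)]
        score = sum(self._weight(k) for k in kmers) / len(kmers)
        return self.scale * math.exp(score)


def predict_baseline(seq: ProteinSequence, substrate_smiles: str,
                     seed: int) -> float:
    """One-shot baseline surrogate call; see :class:`BaselinePredictor`."""
    return BaselinePredictor(seed).predict(seq, substrate_smiles)


def run_scan(seq: ProteinSequence, sites: list[int] | None, predictor,
             substrate_smiles: str,
             predictor_id: str | None = None) -> PredictionTable:
    """Saturation scan: predict kcat for every enumerated single mutant
    plus the wild type.

    ``predictor`` is anything with ``predict(seq, substrate) -> float``.
    The returned table has exactly ``len(mutations) + 1`` records, in
    deterministic order (WT first, then ascending position / alphabetical
    substitution). Predictor failures are re-raised naming the variant.
    """
    table = PredictionTable(
        predictor_id=predictor_id or getattr(predictor, "id",
                                             type(predictor).__name__),
        sequence_id=seq.id,
        substrate_smiles=substrate_smiles,
    )
    mutations = enumerate_saturation(seq, sites)
    table.add("WT", predictor.predict(seq, substrate_smiles))
    for m in mutations:
        variant = Variant.from_mutations([m])
        mutant_seq = apply_variant(seq, variant)
        try:
            kcat = predictor.predict(mutant_seq, substrate_smiles)
        except Exception as exc:
            raise RuntimeError(f"predictor failed on variant {m}") from exc
        table.add(str(m), kcat)
    return table
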