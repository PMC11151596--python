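"""Protein sequences, point mutations and exhaustive saturation enumeration.

Positions are 1-based throughout; ``numbering_offset`` maps a sequence
position to the author numbering of an accompanying crystal structure
(``author_resnum = position + numbering_offset``), so mutation names like
``Q4C`` can refer to the same residue in both frames.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

log = logging.getLogger(__name__)

#: The twenty canonical one-letter amino-acid codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ProteinSequence:
    """A canonical protein sequence with 1-based numbering.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : str
        Uppercase string over the 20 canonical codes.
    numbering_offset : int, default 0
        Added to a 1-based sequence position to obtain the structure's
        author residue number.
    """

    id: str
    residues: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_AA:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside [1, {len(self.residues)}]"
            )
        return self.residues[position - 1]

    def author_resnum(self, position: int) -> int:
        return position + self.numbering_offset


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution ``{wt}{pos}{mut}``, e.g. ``Q4C``."""

    position: int
    wt_aa: str = field(compare=True)
    mut_aa: str = field(compare=True)

    def __post_init__(self) -> None:
        if self.wt_aa not in CANONICAL_AA or self.mut_aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical code in {self.wt_aa}/{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"silent substitution {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        m = _MUTATION_RE.match(token.strip())
        if m is None:
            raise ValueError(f"cannot parse mutation token {token!r}")
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
        return cls(position=pos, wt_aa=wt, mut_aa=mut)


@dataclass(frozen=True)
class Variant:
    """A set of substitutions at distinct positions; empty set is wild-type.

    The canonical label joins mutations with ``/`` in ascending position
    order (``Q4C/T212S/A302C``); the wild-type label is ``WT``.
    """

    mutations: frozenset[Mutation]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError(f"multiple mutations at one position: {self.label}")

    @property
    def label(self) -> str:
        if not self.mutations:
            return "WT"
        return "/".join(str(m) for m in sorted(self.mutations,
                                               key=lambda m: m.position))

    @classmethod
    def from_mutations(cls, mutations) -> "Variant":
        return cls(frozenset(mutations))

    @classmethod
    def parse(cls, label: str) -> "Variant":
        if label.strip().upper() == "WT":
            return cls(frozenset())
        return cls(frozenset(Mutation.parse(t) for t in label.split("/")))

    def __len__(self) -> int:
        return len(self.mutations)


def read_fasta(path) -> list[ProteinSequence]:
    """Read one or more protein records from a FASTA file.

    Sequences are uppercased; any character outside the canonical 20
    raises, naming the offending character, position and record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper())
            for r in records]


def read_mutation_list(path) -> list[Mutation]:
    """Read mutations from a text file, one ``{wt}{pos}{mut}`` token per
    line; ``#`` starts a comment, blank lines are skipped."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(Mutation.parse(line))
    return out


def enumerate_saturation(seq: ProteinSequence,
                         sites: list[int] | None = None) -> list[Mutation]:
    """All 19 substitutions at each scanned site.

    With ``sites=None`` every position of the sequence is scanned, giving
    exactly ``19 * len(seq)`` mutations. Output order is deterministic:
    ascending position, then alphabetical substituting residue. Duplicate
    sites are collapsed with a warning; out-of-range sites raise.
    """
    if sites is None:
        positions = list(range(1, len(seq) + 1))
    else:
        for s in sites:
            if not 1 <= s <= len(seq):
                raise ValueError(
                    f"site {s} outside sequence range [1, {len(seq)}]")
        positions = sorted(set(sites))
        if len(positions) != len(sites):
            log.warning("duplicate sites collapsed: %d given, %d unique",
                        len(sites), len(positions))
    out = []
    for pos in positions:
        wt = seq[pos]
        out.extend(Mutation(position=pos, wt_aa=wt, mut_aa=aa)
                   for aa in CANONICAL_AA if aa != wt)
    return out


def apply_variant(seq: ProteinSequence, variant: Variant) -> ProteinSequence:
    """Return a new sequence with the variant's substitutions applied.

    Every mutation's wild-type residue must match the sequence; the input
    sequence is never modified.
    """
    residues = list(seq.residues)
    for m in variant.mutations:
        if not 1 <= m.position <= len(residues):
            raise ValueError(
                f"{m}: position outside sequence of length {len(residues)}")
        found = residues[m.position - 1]
        if found != m.wt_aa:
            raise ValueError(
                f"{m}: wild-type mismatch at position {m.position} "
                f"(expected {m.wt_aa}, found {found})")
        residues[m.position - 1] = m.mut_aa
    label = seq.id if not variant.mutations else f"{seq.id}_{variant.label.replace('/', '_')}"
    return replace(seq, id=label, residues="".join(residues))
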