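"""Sequence bookkeeping for low-complexity domains.

Composition and residue-distribution profiles, the tyrosine motif/spacing
scan used to reason about aromatic patterning (YxY and YxxY pairs versus
isolated tyrosines), and construction of Y->S substitution mutants.

Residue numbering follows the construct's own scheme: ``start_index`` is the
residue number of the first residue (cloning scars and tags are simply not
part of the string).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_COMPACT_MUT = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter protein sequence with an explicit numbering offset."""

    name: str
    residues: str
    start_index: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValueError(f"non-canonical residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end_index(self) -> int:
        return self.start_index + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue code at a residue *number* (respects start_index)."""
        i = position - self.start_index
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"position {position} outside {self.start_index}..{self.end_index}"
            )
        return self.residues[i]


@dataclass(frozen=True)
class Mutation:
    position: int
    from_aa: str
    to_aa: str

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass
class MutationSet:
    """A labelled set of point substitutions, e.g. the 7YS tyrosine mutant."""

    mutations: list[Mutation]
    label: str = ""

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError("mutation positions must be unique")
        for m in self.mutations:
            if m.from_aa not in _AA_SET or m.to_aa not in _AA_SET:
                raise ValueError(f"non-canonical code in mutation {m}")

    def __len__(self) -> int:
        return len(self.mutations)

    def inverse(self) -> "MutationSet":
        inv = [Mutation(m.position, m.to_aa, m.from_aa) for m in self.mutations]
        return MutationSet(inv, label=f"{self.label}_inverse")

    @classmethod
    def from_strings(cls, specs: Iterable[str], label: str = "") -> "MutationSet":
        """Parse compact strings like ``Y170S`` or delimited ``170,Y,S``."""
        muts = []
        for s in specs:
            s = s.strip()
            if not s or s.startswith("#"):
                continue
            m = _COMPACT_MUT.match(s)
            if m:
                muts.append(Mutation(int(m.group(2)), m.group(1), m.group(3)))
                continue
            parts = [p.strip() for p in re.split(r"[,\t ]+", s)]
            if len(parts) != 3:
                raise ValueError(f"cannot parse mutation spec {s!r}")
            muts.append(Mutation(int(parts[0]), parts[1], parts[2]))
        return cls(muts, label=label)

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "MutationSet":
        path = Path(path)
        lines = path.read_text().splitlines()
        return cls.from_strings(lines, label=label if label is not None else path.stem)


@dataclass(frozen=True)
class MotifHit:
    """A tyrosine spacing class: YxY pair, YxxY pair, or an isolated Y."""

    kind: str  # "YxY" | "YxxY" | "isolated"
    first_position: int
    second_position: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "YxY" and self.second_position - self.first_position != 2:
            raise ValueError("YxY requires spacing 2")
        if self.kind == "YxxY" and self.second_position - self.first_position != 3:
            raise ValueError("YxxY requires spacing 3")
        if self.kind == "isolated" and self.second_position is not None:
            raise ValueError("isolated hits carry a single position")


def composition_profile(seq: ProteinSequence) -> pd.Series:
    """Percent abundance of each of the 20 amino acids (zeros included).

    Returns a Series indexed by one-letter code, summing to exactly 100.
    """
    counts = pd.Series(0, index=list(AMINO_ACIDS), dtype=float)
    for aa in seq.residues:
        counts[aa] += 1
    return 100.0 * counts / len(seq)


def residue_positions(
    seq: ProteinSequence, residue_types: Iterable[str]
) -> dict[str, list[int]]:
    """Residue numbers of each requested residue type, sorted ascending."""
    types = list(residue_types)
    for t in types:
        if t not in _AA_SET:
            raise ValueError(f"unknown residue code {t!r}")
    out: dict[str, list[int]] = {t: [] for t in types}
    for i, aa in enumerate(seq.residues):
        if aa in out:
            out[aa].append(seq.start_index + i)
    return out


def find_tyrosine_motifs(seq: ProteinSequence) -> list[MotifHit]:
    """Classify tyrosine spacings: every YxY (i, i+2) and YxxY (i, i+3) pair
    is reported; tyrosines participating in neither are "isolated".

    A tyrosine may belong to several pairs; counts enumerate pairs, not
    tyrosines.
    """
    ys = residue_positions(seq, ["Y"])["Y"]
    hits: list[MotifHit] = []
    paired: set[int] = set()
    yset = set(ys)
    for p in ys:
        if p + 2 in yset:
            hits.append(MotifHit("YxY", p, p + 2))
            paired.update((p, p + 2))
        if p + 3 in yset:
            hits.append(MotifHit("YxxY", p, p + 3))
            paired.update((p, p + 3))
    for p in ys:
        if p not in paired:
            hits.append(MotifHit("isolated", p))
    hits.sort(key=lambda h: (h.first_position, h.kind))
    return hits


def motif_counts(seq: ProteinSequence) -> dict[str, int]:
    """Summary counts: YxY pairs, YxxY pairs, isolated and total tyrosines."""
    hits = find_tyrosine_motifs(seq)
    return {
        "YxY": sum(h.kind == "YxY" for h in hits),
        "YxxY": sum(h.kind == "YxxY" for h in hits),
        "isolated": sum(h.kind == "isolated" for h in hits),
        "total_tyrosines": seq.residues.count("Y"),
    }


def apply_mutations(seq: ProteinSequence, muts: MutationSet) -> ProteinSequence:
    """Apply point substitutions; every from_aa must match the sequence."""
    residues = list(seq.residues)
    for m in muts.mutations:
        i = m.position - seq.start_index
        if not 0 <= i < len(residues):
            raise IndexError(f"mutation {m} outside {seq.start_index}..{seq.end_index}")
        if residues[i] != m.from_aa:
            raise ValueError(
                f"mutation {m}: sequence has {residues[i]} at position "
                f"{m.position} (wrong numbering convention?)"
            )
        residues[i] = m.to_aa
    name = f"{seq.name}_{muts.label}" if muts.label else seq.name
    return ProteinSequence(name, "".join(residues), seq.start_index)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read one or more records from a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(r.id, str(r.seq).upper()) for r in records]


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
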