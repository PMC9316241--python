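"""Sequence records and species-labeled reference panels.

A reference panel is a set of aligned mtDNA barcode haplotypes (e.g. ~685 bp
COII amplicons), each anchored to a species name by integrative taxonomy.
Panels are read from FASTA with ``>{species}|{suffix}`` headers; queries are
plain FASTA records whose species, if known, travels in ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

#: Characters permitted in an aligned barcode sequence. ``N`` is an ambiguous
#: base and ``-`` an alignment gap; both are ignored pairwise in distances.
ALPHABET = frozenset("ACGTN-")
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned nucleotide sequence with an optional species label."""

    id: str
    bases: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} has no bases")
        bases = self.bases.upper()
        bad = set(bases) - ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(bases) if b in bad)
            raise ValueError(
                f"sequence {self.id!r} has invalid character {bases[pos]!r} "
                f"at position {pos}"
            )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)


class ReferencePanel:
    """Species-labeled aligned reference haplotypes.

    Every species carries at least one reference and all references share one
    aligned length — the two invariants nearest-reference assignment relies on.
    """

    def __init__(self, references: dict[str, list[SequenceRecord]]):
        if not references:
            raise ValueError("reference panel is empty")
        lengths = set()
        seen_ids: set[str] = set()
        for species, recs in references.items():
            if not recs:
                raise ValueError(f"species {species!r} has zero references")
            for r in recs:
                if r.id in seen_ids:
                    raise ValueError(f"duplicate reference id {r.id!r}")
                seen_ids.add(r.id)
                lengths.add(len(r))
        if len(lengths) != 1:
            raise ValueError(f"reference lengths differ: {sorted(lengths)}")
        self._refs = {sp: list(recs) for sp, recs in references.items()}
        self._length = lengths.pop()

    @property
    def species(self) -> list[str]:
        return list(self._refs)

    @property
    def alignment_length(self) -> int:
        return self._length

    @property
    def n_references(self) -> int:
        return sum(len(v) for v in self._refs.values())

    def references(self, species: str) -> list[SequenceRecord]:
        return list(self._refs[species])

    def all_records(self) -> list[SequenceRecord]:
        return [r for recs in self._refs.values() for r in recs]

    def __iter__(self) -> Iterator[tuple[str, list[SequenceRecord]]]:
        return iter(self._refs.items())

    def __contains__(self, species: str) -> bool:
        return species in self._refs

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "ReferencePanel":
        by_species: dict[str, list[SequenceRecord]] = {}
        for r in records:
            if r.label is None:
                raise ValueError(f"reference {r.id!r} has no species label")
            by_species.setdefault(r.label, []).append(r)
        return cls(by_species)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        """Read a panel whose headers follow ``>{species}|{suffix}``."""
        records = []
        for rec in read_fasta(path):
            if "|" not in rec.id:
                raise ValueError(
                    f"panel header {rec.id!r} lacks a '|' species separator"
                )
            species = rec.id.split("|", 1)[0]
            records.append(SequenceRecord(rec.id, rec.bases, label=species))
        return cls.from_records(records)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(self.all_records(), path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords; labels are left unset."""
    return [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.bases), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")
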