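"""Protein records and FASTA I/O.

A :class:`ProteinRecord` is the atomic unit of every scan: an identifier,
an optional species tag and an uppercase amino-acid sequence over the 20
standard letters plus the ambiguity/rare letters X, U, B and Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = set("XUBZ")
VALID_AA = STANDARD_AA | AMBIGUOUS_AA


class SequenceError(ValueError):
    """Raised for malformed sequences or records."""


def validate_sequence(seq: str) -> None:
    """Reject empty sequences and non-amino-acid characters.

    The error names the first offending 0-based position so malformed
    FASTA input is diagnosable.
    """
    if not seq:
        raise SequenceError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_AA:
            raise SequenceError(
                f"invalid character {ch!r} at position {i} "
                "(expected an uppercase amino-acid letter)"
            )


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    seq: str
    species: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("empty protein id")
        validate_sequence(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a multi-record FASTA file into a list of :class:`ProteinRecord`.

    The record id is the first whitespace-delimited token of the
    description line. Sequences are uppercased; duplicate ids or an
    empty file raise :class:`SequenceError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), species))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = (
        SeqRecord(Seq(r.seq), id=r.id, description=r.species) for r in records
    )
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def iter_proteomes(
    paths_by_species: dict[str, str | Path],
) -> Iterator[tuple[str, list[ProteinRecord]]]:
    """Yield (species, records) for each configured proteome FASTA."""
    for species, path in paths_by_species.items():
        yield species, read_fasta(path, species=species)
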