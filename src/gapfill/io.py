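"""FASTA input/output and the scaffold record type.

Scaffolds are plain named nucleotide strings over {A,C,G,T,N}. At read
time lowercase letters are uppercased and IUPAC ambiguity codes other
than N are mapped to N; ``strict=True`` rejects them instead. This keeps
every downstream consumer (encoder, model, search) on a five-letter
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")
# IUPAC one-letter ambiguity codes that collapse to N under the relaxed policy.
_AMBIGUITY = frozenset("RYSWKMBDHVU")


class FastaParseError(ValueError):
    """Malformed FASTA content; message carries the offending entry/position."""


@dataclass(frozen=True)
class ScaffoldRecord:
    """A named nucleotide sequence, possibly containing N-runs (gaps)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str, *, strict: bool = False, context: str = "") -> str:
    """Uppercase and map ambiguity codes to N; reject anything unknown.

    With ``strict`` any character outside {A,C,G,T,N} raises.
    """
    up = seq.upper()
    if set(up) <= ALPHABET:
        return up
    out = []
    for i, ch in enumerate(up):
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUITY and not strict:
            out.append("N")
        else:
            where = f" in {context}" if context else ""
            raise FastaParseError(f"illegal character {ch!r} at position {i}{where}")
    return "".join(out)


def read_fasta(path: str | Path, *, strict: bool = False) -> list[ScaffoldRecord]:
    """Read a (multi-)FASTA file into ScaffoldRecords, order preserved."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: entry without an identifier")
        seq = normalize_sequence(str(rec.seq), strict=strict, context=f"record {rec.id!r}")
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ScaffoldRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(
    records: Iterable[ScaffoldRecord], path: str | Path, line_width: int = 60
) -> None:
    """Write records as wrapped FASTA; round-trips id and sequence exactly."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    path = Path(path)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(
            SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
        )
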