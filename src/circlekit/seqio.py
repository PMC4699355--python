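"""FASTA/FASTQ input/output and elementary sequence operations.

All coordinates inside the package are 0-based half-open on the forward
strand.  Conversion to 1-based inclusive coordinates happens only when
show-coords-style tables are written (see :mod:`circlekit.align`), matching
the MUMmer convention the decision-rule thresholds were written against.

Sequences are uppercased on read and restricted to the alphabet
``{A, C, G, T, N}``; anything else is rejected rather than silently masked,
so alignment semantics stay unambiguous.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqError(ValueError):
    """Base class for sequence validation problems."""


class ParseError(SeqError):
    """Raised when a file cannot be parsed as the named format."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with Phred+33 qualities.

    Qualities are carried through untouched but never interpreted.
    """

    id: str
    seq: str
    qual: str | None = None
    desc: str = ""

    def validate(self) -> "SeqRecord":
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqError(f"invalid record id: {self.id!r}")
        if len(self.seq) < 1:
            raise SeqError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise SeqError(
                f"record {self.id!r} contains invalid characters: {sorted(bad)}"
            )
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise SeqError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        return self

    def __len__(self) -> int:
        return len(self.seq)


def _sniff_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    return "fasta"


def read_seqs(path: str, format: str = "auto") -> list[SeqRecord]:
    """Read an ordered collection of records from a FASTA/FASTQ file.

    Duplicate ids raise :class:`SeqError`; malformed records raise
    :class:`ParseError` naming the offending record where known.
    """
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    out: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(_BioSeqIO.parse(path, fmt)):
            qual = None
            if fmt == "fastq":
                phred = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(q + 33) for q in phred)
            desc = rec.description[len(rec.id):].strip()
            out.append(
                SeqRecord(rec.id, str(rec.seq).upper(), qual, desc).validate()
            )
    except SeqError:
        raise
    except ValueError as exc:  # Biopython parse failure
        raise ParseError(f"{path}: record {len(out) + 1}: {exc}") from exc
    for rec in out:
        if rec.id in seen:
            raise SeqError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
    if not out:
        raise ParseError(f"{path}: no records parsed as {fmt}")
    return out


def write_seqs(records: Iterable[SeqRecord], path: str,
               format: str = "auto") -> None:
    """Write records as FASTA (wrapped at 60 columns) or FASTQ."""
    records = list(records)
    if format == "auto":
        format = "fastq" if all(r.qual is not None for r in records) else "fasta"
    bio = []
    for r in records:
        b = _BioSeqRecord(_BioSeq(r.seq), id=r.id, description=r.desc)
        if format == "fastq":
            if r.qual is None:
                raise SeqError(f"record {r.id!r} has no qualities for FASTQ")
            b.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in r.qual
            ]
        bio.append(b)
    with open(path, "w") as fh:
        _BioSeqIO.write(bio, fh, format)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise SeqError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, new_start: int) -> str:
    """Rotate so that ``new_start`` becomes position 0 (circular shift)."""
    if not 0 <= new_start < len(seq):
        raise SeqError(
            f"rotation offset {new_start} out of range for length {len(seq)}"
        )
    return seq[new_start:] + seq[:new_start]
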