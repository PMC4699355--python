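"""The working contig type shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import SeqRecord


@dataclass
class Contig:
    """A named sequence with a circularity flag and a provenance trail.

    Provenance entries record how the contig came to be: merges
    (``merged_from:<a>+<b>``), circularization (``replaced_by:<unit>``,
    ``end_joined_via:<unit>``), trimming and rotation.
    """

    id: str
    seq: str
    circular: bool = False
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.seq)

    def with_event(self, event: str, **changes) -> "Contig":
        d = dict(id=self.id, seq=self.seq, circular=self.circular,
                 provenance=self.provenance + (event,))
        d.update(changes)
        return Contig(**d)

    def to_seqrecord(self) -> SeqRecord:
        desc = "circular=true" if self.circular else ""
        return SeqRecord(self.id, self.seq, desc=desc)

    @classmethod
    def from_seqrecord(cls, rec: SeqRecord) -> "Contig":
        return cls(rec.id, rec.seq, circular="circular=true" in rec.desc)
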