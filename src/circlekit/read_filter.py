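"""Select and trim corrected reads near contig ends for local reassembly.

Only the ends of long contigs need reassembling: for contigs at least
``length_cutoff`` bases long (default 100,000), reads mapping wholly
within the first or last ``end_window`` bases (default 50,000) are kept,
reads crossing a window boundary are trimmed back to the part aligned
inside the window (kept only if at least ``min_trimmed_len`` bases remain,
default 250), and purely interior reads are discarded.  Reads whose best
mapping is to a short contig, and unmapped reads, are kept whole.

"Maps to" means the read's primary hit: the one maximising
``aln_len * pct_id``.  Trimming cuts the read at the base aligned to the
window boundary; unaligned read overhangs beyond the contig end are kept,
since those bases may bridge the circle.  A read overlapping both windows
of one contig yields one trimmed record per end, with suffixed ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .align import Hit
from .seqio import SeqRecord


@dataclass
class ReadRecord:
    id: str
    seq: str
    source_read: str
    trimmed: bool = False
    origin: str = "unmapped"  # end_window | short_contig | unmapped

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.trimmed and self.origin != "end_window":
            raise ValueError("trimmed reads can only originate from end windows")

    def __len__(self) -> int:
        return len(self.seq)

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(self.id, self.seq)


@dataclass
class FilterParams:
    length_cutoff: int = 100_000
    end_window: int = 50_000
    min_trimmed_len: int = 250

    def __post_init__(self) -> None:
        for name in ("length_cutoff", "end_window", "min_trimmed_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def primary_hit(hits: Sequence[Hit]) -> Hit | None:
    """The hit maximising aln_len * pct_id (ties: lowest ref id/start)."""
    if not hits:
        return None
    return max(hits, key=lambda h: (h.aln_len * h.pct_id,
                                    h.ref_id, -h.ref_start), default=None)


def _read_cut(h: Hit, contig_pos: int) -> int:
    """Read-forward coordinate aligned to ``contig_pos`` (colinear map)."""
    off = contig_pos - h.ref_start
    if h.strand == "+":
        return h.qry_start + off
    return h.qry_end - off


def filter_reads(reads: Sequence[SeqRecord], contigs: Sequence[SeqRecord],
                 hits: Sequence[Hit],
                 params: FilterParams | None = None) -> list[ReadRecord]:
    """Apply the end-window retention rule.  ``hits`` map reads (query)
    onto contigs (reference)."""
    if params is None:
        params = FilterParams()
    contig_len = {c.id: len(c.seq) for c in contigs}
    by_read: dict[str, list[Hit]] = {}
    for h in hits:
        if h.ref_id not in contig_len:
            raise ValueError(f"hit references unknown contig {h.ref_id!r}")
        by_read.setdefault(h.qry_id, []).append(h)
    read_ids = {r.id for r in reads}
    for rid in by_read:
        if rid not in read_ids:
            raise ValueError(f"hit references unknown read {rid!r}")

    out: list[ReadRecord] = []
    for read in reads:
        rhits = by_read.get(read.id, [])
        best = primary_hit(rhits)
        if best is None:
            out.append(ReadRecord(read.id, read.seq, read.id,
                                  origin="unmapped"))
            continue
        # a read placing equally well at several positions (repeated
        # sequence) keeps the placement that avoids trimming, when one
        # exists; this is what a mapper's arbitrary primary placement
        # achieves in expectation, made deterministic
        score = best.aln_len * best.pct_id
        ties = [h for h in rhits if h.aln_len * h.pct_id >= score * 0.999]
        if len(ties) > 1:
            def untrimmed(h):
                cl = contig_len[h.ref_id]
                w_ = params.end_window
                return (cl < params.length_cutoff or cl <= 2 * w_
                        or h.ref_end <= w_ or h.ref_start >= cl - w_)
            whole = [h for h in ties if untrimmed(h)]
            if whole:
                best = min(whole, key=lambda h: (h.ref_id, h.ref_start))
            else:
                # every candidate placement crosses a window boundary
                # (tandem repeats commensurate with the windows): the
                # trim position is placement-dependent and therefore
                # unjustified; keep the read whole
                out.append(ReadRecord(read.id, read.seq, read.id,
                                      origin="end_window"))
                continue
        clen = contig_len[best.ref_id]
        if clen < params.length_cutoff:
            out.append(ReadRecord(read.id, read.seq, read.id,
                                  origin="short_contig"))
            continue
        w = params.end_window
        if clen <= 2 * w:
            # the end windows tile the whole contig: nothing to trim away
            out.append(ReadRecord(read.id, read.seq, read.id,
                                  origin="end_window"))
            continue
        rs, re = best.ref_start, best.ref_end
        if re <= w or rs >= clen - w:
            # mapping wholly inside one end window: keep whole
            out.append(ReadRecord(read.id, read.seq, read.id,
                                  origin="end_window"))
            continue
        if rs >= w and re <= clen - w:
            continue  # wholly interior
        both = rs < w and re > clen - w
        if rs < w:
            # crosses the start-window boundary: keep the start-side part
            cut = _read_cut(best, w)
            if best.strand == "+":
                sub = read.seq[:cut]
            else:
                sub = read.seq[cut:]
            if len(sub) >= params.min_trimmed_len:
                rid = f"{read.id}.left" if both else read.id
                out.append(ReadRecord(rid, sub, read.id, trimmed=True,
                                      origin="end_window"))
        if re > clen - w:
            cut = _read_cut(best, clen - w)
            if best.strand == "+":
                sub = read.seq[cut:]
            else:
                sub = read.seq[:cut]
            if len(sub) >= params.min_trimmed_len:
                rid = f"{read.id}.right" if both else read.id
                out.append(ReadRecord(rid, sub, read.id, trimmed=True,
                                      origin="end_window"))
    return out
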